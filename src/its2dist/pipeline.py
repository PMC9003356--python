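"""End-to-end orchestration: screen -> consensus -> partition -> model test
-> distances -> CBC/rate report.

The pipeline takes a genus-level set of aligned sequence-structure records
(or a synthetic genus), screens it for sister species pairs, and for every
SSP builds the consensus structure, partitions the alignment, runs the mixed
model grid, and reports GD_DNA, GD_RNA, their ratio, raw stem/loop rates and
CBC counts.  SSPs with no stem or no loop variation are excluded from the
RNA stage and listed separately.  All thresholds are configuration, with the
field-standard values as defaults; outputs are TSV tables plus a JSON run
log, and identical config + seed give identical output bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cbc import count_cbc, substitution_rates, variable_site_table
from .distance import count_patterns, gd_ratio
from .errors import Its2DistError
from .modelselect import (
    DEFAULT_DNA_ROSTER,
    DEFAULT_LOOP_ROSTER,
    DEFAULT_STEM_ROSTER,
    grid_search,
)
from .njscreen import bootstrap_support, screen_genus
from .seqstruct import (
    Alignment,
    consensus_structure,
    partition_alignment,
    read_vienna,
)
from .simulate import SimConfig, simulate_genus

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs; thresholds default to the field values."""

    seed: int
    outdir: Optional[str] = None
    vienna_path: Optional[str] = None
    species_map_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    n_species: int = 4
    consensus_threshold: float = 0.75
    resolution_threshold: float = 0.5
    support_threshold: float = 50.0
    bootstrap_replicates: int = 1000
    loop_roster: tuple[str, ...] = DEFAULT_LOOP_ROSTER
    stem_roster: tuple[str, ...] = DEFAULT_STEM_ROSTER
    dna_roster: tuple[str, ...] = DEFAULT_DNA_ROSTER

    def __post_init__(self):
        if not (0.5 < self.consensus_threshold <= 1.0):
            raise ValueError("consensus threshold must lie in (0.5, 1.0]")
        if not (0.0 <= self.resolution_threshold <= 1.0):
            raise ValueError("resolution threshold must lie in [0, 1]")
        if not (0.0 <= self.support_threshold <= 100.0):
            raise ValueError("support threshold must lie in [0, 100]")
        if self.vienna_path is None and self.sim is None:
            raise ValueError("either input paths or a simulation config is required")


def _load_inputs(cfg: PipelineConfig) -> tuple[Alignment, dict[str, list[str]]]:
    if cfg.vienna_path is not None:
        records = read_vienna(Path(cfg.vienna_path).read_text())
        aln = Alignment(tuple(records))
        species_map: dict[str, list[str]] = {}
        if cfg.species_map_path is not None:
            for ln in Path(cfg.species_map_path).read_text().splitlines():
                if not ln.strip() or ln.startswith("#"):
                    continue
                rid, sp = ln.split("\t")[:2]
                species_map.setdefault(sp, []).append(rid)
        else:
            # default convention: individual ids look like "<species>_<n>"
            for r in records:
                sp = r.id.rsplit("_", 1)[0]
                species_map.setdefault(sp, []).append(r.id)
        return aln, species_map
    return simulate_genus(cfg.sim, cfg.n_species)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a report bundle of DataFrames.

    Keys: ``ssp_table``, ``model_table``, ``exclusions``, ``screen``,
    ``tree_newick``, ``log``.  When ``cfg.outdir`` is set the tables are also
    written as TSV plus a machine-readable JSON log of every threshold used.
    """
    aln, species_map = _load_inputs(cfg)
    tree = bootstrap_support(aln, replicates=cfg.bootstrap_replicates, seed=cfg.seed)
    screen = screen_genus(tree, species_map)
    ssp_rows, model_rows, exclusion_rows = [], [], []
    for ssp in screen.ssps:
        pair_id = f"{ssp.species_a}-{ssp.species_b}"
        try:
            members = sorted(species_map[ssp.species_a]) + sorted(species_map[ssp.species_b])
            sub = aln.subset(members)
            cons = consensus_structure(sub, cfg.consensus_threshold)
            mask = partition_alignment(sub, cons)
            rep_a = min(species_map[ssp.species_a])
            rep_b = min(species_map[ssp.species_b])
            pair = sub.subset([rep_a, rep_b])
            var = variable_site_table(pair, mask)
            if var["stem_variable"] == 0 or var["loop_variable"] == 0:
                exclusion_rows.append({
                    "pair_id": pair_id,
                    "reason": ("no stem variation" if var["stem_variable"] == 0
                               else "no loop variation"),
                    **var,
                })
                continue
            fits = grid_search(pair, mask, cfg.loop_roster, cfg.stem_roster, cfg.dna_roster)
            for rank, f in enumerate(fits, 1):
                model_rows.append({
                    "pair_id": pair_id,
                    "loop_model": f.loop_model,
                    "stem_model": f.stem_model or ".",
                    "lnl_raw": f.lnl_raw,
                    "lnl_corrected": f.lnl_corrected,
                    "k": f.k,
                    "n": f.n,
                    "aicc": f.aicc,
                    "rank": rank,
                })
            best_mixed = next(f for f in fits if f.stem_model is not None)
            best_dna = next(f for f in fits if f.stem_model is None)
            rates = substitution_rates(pair, mask)
            cbc = count_cbc(pair[0], pair[1], cons)
            ssp_rows.append({
                "pair_id": pair_id,
                "rep_a": rep_a,
                "rep_b": rep_b,
                "support": ssp.support,
                "gd_dna": best_dna.result.gd,
                "gd_rna": best_mixed.result.gd,
                "gd_ratio": gd_ratio(best_mixed.result, best_dna.result),
                "srs": rates.srs,
                "srl": rates.srl,
                "srs_srl": rates.ratio_or_none,
                "cbc": cbc.cbc,
                "hemi_cbc": cbc.hemi_cbc,
                "best_dna_model": best_dna.label,
                "best_rna_model": best_mixed.label,
                "lnl_dna": best_dna.lnl_corrected,
                "lnl_rna": best_mixed.lnl_corrected,
                "aicc_dna": best_dna.aicc,
                "aicc_rna": best_mixed.aicc,
                "t_loop": best_mixed.result.t_loop,
                "t_stem": best_mixed.result.t_stem,
            })
        except Its2DistError as e:
            logger.warning("SSP %s failed at analysis stage: %s", pair_id, e)
            exclusion_rows.append({"pair_id": pair_id, "reason": str(e)})
    bundle = {
        "ssp_table": pd.DataFrame(ssp_rows),
        "model_table": pd.DataFrame(model_rows),
        "exclusions": pd.DataFrame(exclusion_rows),
        "screen": screen,
        "tree_newick": tree.newick(),
        "log": {
            "seed": cfg.seed,
            "consensus_threshold": cfg.consensus_threshold,
            "resolution_threshold": cfg.resolution_threshold,
            "support_threshold": cfg.support_threshold,
            "bootstrap_replicates": cfg.bootstrap_replicates,
            "loop_roster": list(cfg.loop_roster),
            "stem_roster": list(cfg.stem_roster),
            "dna_roster": list(cfg.dna_roster),
            "n_records": len(aln),
            "n_columns": aln.columns,
            "species_resolution": screen.resolution,
            "genus_passes": screen.resolution >= cfg.resolution_threshold,
            "n_ssps_screened": len(screen.ssps),
            "n_ssps_reported": len(ssp_rows),
            "n_ssps_excluded": len(exclusion_rows),
        },
    }
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("ssp_table", "model_table", "exclusions"):
            bundle[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
        (out / "tree.nwk").write_text(bundle["tree_newick"] + "\n")
        (out / "run_log.json").write_text(json.dumps(bundle["log"], indent=2) + "\n")
    return bundle
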