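"""Three-step bait-anchored ratiometric filtering of the proximity-labeling interactome.

Starting from all detected proteins, the filter (1) keeps proteins
identified by at least ``k`` unique peptides, (2) removes endogenously
biotinylated / endogenous-peroxidase contaminants by keeping only proteins
whose bait/NC fold change is at least the bait's own (the bait anchors its
own enrichment scale), and (3) removes generic membrane-proximal background
by keeping proteins with a strictly positive bait/SR fold change.  The
surviving set is the bait's intracellular interactome; candidates are
ranked by bait/SR fold change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import pandas as pd

from .tmt import TmtDesign, analyze_quant_table

logger = logging.getLogger(__name__)


@dataclass
class FilterTrace:
    """Protein counts surviving each filter step (nested subsets)."""

    bait_id: str
    n_detected: int = 0
    n_step1: int = 0
    n_step2: int = 0
    n_step3: int = 0
    bait_fc_nc: float = float("nan")

    def validate(self) -> None:
        if not (self.n_detected >= self.n_step1 >= self.n_step2 >= self.n_step3 >= 0):
            raise AssertionError(
                f"filter steps must be nested: {self.n_detected} >= {self.n_step1} "
                f">= {self.n_step2} >= {self.n_step3}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def filter_min_unique_peptides(proteins: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Step 1: retain proteins identified by >= k unique peptides."""
    return proteins[proteins["unique_peptides"] >= k].copy()


def bait_anchor_filter(
    fits: pd.DataFrame,
    bait_id: str,
    match_on: Literal["protein_id", "gene_symbol"] = "protein_id",
) -> pd.DataFrame:
    """Step 2: retain proteins with fc_nc >= the bait's own fc_nc (inclusive).

    The bait always retains itself (fc >= itself).  Raises if the bait is
    absent from the fits.
    """
    hit = fits[fits[match_on] == bait_id]
    if hit.empty:
        raise KeyError(f"bait {bait_id!r} not found by {match_on} in model fits")
    bait_fc = float(hit["fc_nc"].iloc[0])
    return fits[fits["fc_nc"] >= bait_fc].copy()


def sr_ratiometric_filter(fits: pd.DataFrame) -> pd.DataFrame:
    """Step 3: retain proteins with strictly positive bait/SR fold change."""
    return fits[fits["fc_sr"] > 0].copy()


def rank_candidates(interactome: pd.DataFrame, k: int = 37) -> pd.DataFrame:
    """Rank the filtered interactome by descending fc_sr; return the top k.

    Ties are broken by smaller q_sr, then lexicographic protein_id, so the
    ordering is deterministic.  If k exceeds the set size the full sorted
    set is returned with a warning.
    """
    cols = ["fc_sr"]
    asc = [False]
    if "q_sr" in interactome.columns:
        cols.append("q_sr")
        asc.append(True)
    cols.append("protein_id")
    asc.append(True)
    ranked = interactome.sort_values(cols, ascending=asc, kind="mergesort").reset_index(
        drop=True
    )
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    if k > len(ranked):
        logger.warning(
            "requested top %d but interactome has only %d proteins", k, len(ranked)
        )
        return ranked
    return ranked.head(k).copy()


@dataclass
class InteractomeResult:
    stats: pd.DataFrame
    interactome: pd.DataFrame
    shortlist: pd.DataFrame
    trace: FilterTrace


def apply_filters(
    fits: pd.DataFrame,
    bait_id: str,
    min_peptides: int = 2,
    top_k: int = 37,
    match_on: Literal["protein_id", "gene_symbol"] = "protein_id",
) -> InteractomeResult:
    """Run the three filter steps plus ranking on moderated model fits."""
    trace = FilterTrace(bait_id=bait_id, n_detected=len(fits))
    step1 = filter_min_unique_peptides(fits, k=min_peptides)
    trace.n_step1 = len(step1)
    step2 = bait_anchor_filter(step1, bait_id, match_on=match_on)
    trace.n_step2 = len(step2)
    trace.bait_fc_nc = float(
        step2.loc[step2[match_on] == bait_id, "fc_nc"].iloc[0]
    )
    step3 = sr_ratiometric_filter(step2)
    trace.n_step3 = len(step3)
    trace.validate()
    shortlist = rank_candidates(step3, k=top_k)
    return InteractomeResult(
        stats=fits, interactome=step3, shortlist=shortlist, trace=trace
    )


def run_interactome(
    table: pd.DataFrame,
    design: TmtDesign,
    bait_id: str,
    min_peptides: int = 2,
    top_k: int = 37,
    mode: Literal["raw_intensity", "precomputed"] = "precomputed",
    match_on: Literal["protein_id", "gene_symbol"] = "protein_id",
) -> InteractomeResult:
    """End-to-end: model the quant table, then filter and rank."""
    fits, _prior, _report = analyze_quant_table(table, design, mode=mode)
    return apply_filters(
        fits, bait_id, min_peptides=min_peptides, top_k=top_k, match_on=match_on
    )


def write_result(result: InteractomeResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the trace JSON and the three TSVs; returns emitted paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace": out / "filter_trace.json",
        "stats": out / "protein_stats.tsv",
        "interactome": out / "interactome.tsv",
        "shortlist": out / "shortlist.tsv",
    }
    result.trace.to_json(paths["trace"])
    result.stats.to_csv(paths["stats"], sep="\t", index=False)
    result.interactome.to_csv(paths["interactome"], sep="\t", index=False)
    result.shortlist.to_csv(paths["shortlist"], sep="\t", index=False)
    return paths
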