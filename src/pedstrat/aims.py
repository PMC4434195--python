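"""Ancestry-informative marker (AIM) selection.

Divergent family pairs are read off the PC structure (the families with the
extreme mean scores on each chosen component), and markers are ranked by the
delta statistic — the absolute difference of the *same* allele's frequency in
the two families, δ = |p1 − p2|.  Markers with δ above a cutoff (0.6 by
default, the threshold conventionally regarded as highly ancestry-informative)
form the AIM panel.

Both frequencies use the fixed alternate-allele orientation from the variant
metadata.  Flipping each group to its own minor allele would make δ
asymmetric and can manufacture spurious large values near p = 0.5, so it is
never done.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genoio import GenotypeMatrix, Pedigree, compute_freq
from .pca import PCAResult

__all__ = [
    "DEFAULT_DELTA_CUTOFF",
    "AIMPanel",
    "family_pc_means",
    "find_divergent_pairs",
    "pair_frequencies",
    "select_aims",
    "merge_panels",
    "write_panel",
]

log = logging.getLogger(__name__)

DEFAULT_DELTA_CUTOFF = 0.6


@dataclass
class AIMPanel:
    """Markers surviving the delta cutoff for one family pair.

    ``records`` columns: ``variant_id, p1, p2, delta``, sorted by descending
    delta (ties by variant id)."""

    group1: str
    group2: str
    cutoff: float
    records: pd.DataFrame
    n_skipped_undefined: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return self.records["variant_id"].tolist()

    def __len__(self) -> int:
        return len(self.records)


def family_pc_means(result: PCAResult, pedigree: Pedigree) -> pd.DataFrame:
    """Arithmetic mean score per family per component (index fid, columns
    PC1..PCk)."""
    fid_of = pedigree.family_of()
    unknown = set(result.sample_ids["iid"]) - set(fid_of.index)
    if unknown:
        raise ValueError(f"scored individuals without a family: {sorted(unknown)[:5]}")
    df = pd.DataFrame(
        result.scores,
        columns=[f"PC{j+1}" for j in range(result.n_components)],
    )
    df["fid"] = fid_of.loc[result.sample_ids["iid"]].to_numpy()
    return df.groupby("fid").mean()


def find_divergent_pairs(
    family_means: pd.DataFrame,
    components: Sequence[int] = (1, 2),
    n_pairs_per_component: int = 1,
) -> list[tuple[str, str]]:
    """For each listed component (1-based), the (lowest-mean, highest-mean)
    family pair; successive pairs per component take the next most extreme
    families.  Pairs are deduplicated across components, ties broken by
    family id order."""
    if len(family_means) < 2:
        raise ValueError("need at least 2 families to find a divergent pair")
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for comp in components:
        col = f"PC{comp}"
        if col not in family_means.columns:
            raise ValueError(f"component {comp} not in family means")
        # stable sort on (value, fid) gives a deterministic tie-break
        order = family_means[col].reset_index().sort_values(
            [col, "fid"], kind="stable"
        )["fid"].tolist()
        for r in range(n_pairs_per_component):
            lo, hi = order[r], order[-1 - r]
            if lo == hi:
                break
            key = frozenset((lo, hi))
            if key in seen:
                log.info("pair (%s, %s) already selected on an earlier PC", lo, hi)
                continue
            seen.add(key)
            pairs.append((lo, hi))
    return pairs


def pair_frequencies(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    pair: tuple[str, str],
    founders_only: bool = False,
) -> pd.DataFrame:
    """Alt-allele frequency table restricted to the two families of ``pair``.

    By default frequencies are computed over all family members, relatives
    included; ``founders_only`` restricts to founders to avoid counting
    transmitted copies repeatedly."""
    t = pedigree.table
    mask = t["fid"].isin(pair)
    if founders_only:
        mask &= t["founder"]
    members = t[mask]
    grouping = pd.Series(members["fid"].to_numpy(), index=members["iid"].to_numpy())
    grouping = grouping[grouping.index.isin(matrix.iids)]
    return compute_freq(matrix.subset_individuals(grouping.index.tolist()), grouping)


def select_aims(
    freq_table: pd.DataFrame,
    cutoff: float = DEFAULT_DELTA_CUTOFF,
    provenance: dict | None = None,
) -> AIMPanel:
    """All variants with δ = |p1 − p2| strictly above ``cutoff``, sorted by
    descending delta.  ``freq_table`` must contain exactly two group labels;
    variants with an undefined frequency in either group are skipped (count
    recorded).  An empty result is a valid panel, not an error."""
    groups = sorted(freq_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"frequency table must have exactly 2 groups, got {groups}")
    g1, g2 = groups
    wide = freq_table.pivot(index="variant_id", columns="group", values="p_alt")
    defined = wide.notna().all(axis=1)
    n_skipped = int((~defined).sum())
    if n_skipped:
        log.info("skipping %d variants with undefined frequency in a group", n_skipped)
    wide = wide[defined]
    delta = (wide[g1] - wide[g2]).abs()
    sel = delta[delta > cutoff]
    records = (
        pd.DataFrame(
            {
                "variant_id": sel.index,
                "p1": wide.loc[sel.index, g1].to_numpy(),
                "p2": wide.loc[sel.index, g2].to_numpy(),
                "delta": sel.to_numpy(),
            }
        )
        .sort_values(["delta", "variant_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    if records.empty:
        log.warning("no variants passed delta > %s for pair (%s, %s)", cutoff, g1, g2)
    return AIMPanel(g1, g2, cutoff, records, n_skipped, provenance or {})


def merge_panels(panels: Sequence[AIMPanel], deduplicate: bool = True) -> list[str]:
    """Union of panel variant ids, preserving descending-delta order within
    each source panel; duplicates across panels dropped by default (keep
    first occurrence)."""
    out: list[str] = []
    seen: set[str] = set()
    for panel in panels:
        for vid in panel.variant_ids:
            if deduplicate and vid in seen:
                continue
            seen.add(vid)
            out.append(vid)
    return out


def write_panel(panel: AIMPanel, path: str | Path, seed: int | None = None) -> None:
    df = panel.records.copy()
    df.insert(1, "group1", panel.group1)
    df.insert(2, "group2", panel.group2)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(f"# cutoff={panel.cutoff} skipped_undefined={panel.n_skipped_undefined}\n")
        df.to_csv(fh, sep="\t", index=False)
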