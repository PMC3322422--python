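"""Sharing of the founder risk haplotype from unphased genotypes.

An unphased genotype cannot reveal which of a carrier's two chromosomes holds
the founder-risk allele at a site, so a heterozygous (dosage 1) or
homozygous-risk (dosage 2) genotype is always *consistent* with carriage of
the founder haplotype at that site; only a homozygous non-risk genotype
(dosage 0) refutes carriage.  Missing genotypes neither refute nor add
evidence.

For each sample we report the maximal contiguous run of non-refuting markers
that brackets the expansion locus, and measure the sharing extent from the
locus to the outermost *consistent* marker on each side, in bp and in cM.
This is the per-individual horizontal "sharing bar" of a founder-haplotype
decay plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerPanel

__all__ = [
    "Consistency",
    "ShareResult",
    "ShareSummary",
    "site_consistency",
    "consistency_flags",
    "share_interval",
    "cohort_share",
    "shares_to_frame",
    "consistency_matrix_frame",
]


class Consistency(Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    MISSING = "missing"


def site_consistency(dosage: float) -> Consistency:
    """Consistency of one unphased dosage with founder-haplotype carriage.

    A dosage of 1 or 2 means at least one risk allele is present, which one
    of the two phasings can place on the expansion chromosome; dosage 0
    refutes carriage at the site.
    """
    if dosage is None or (isinstance(dosage, float) and np.isnan(dosage)):
        return Consistency.MISSING
    if dosage in (1, 2):
        return Consistency.CONSISTENT
    if dosage == 0:
        return Consistency.INCONSISTENT
    raise ValueError(f"invalid dosage {dosage!r}")


def consistency_flags(dosages: np.ndarray) -> np.ndarray:
    """Vectorised per-marker flags: 1 consistent, 0 inconsistent, -1 missing."""
    d = np.asarray(dosages, dtype=float)
    flags = np.where(np.isnan(d), -1, np.where(d >= 1, 1, 0))
    return flags.astype(np.int8)


@dataclass
class ShareResult:
    """Sharing extent of one sample around the expansion locus.

    ``left_index``/``right_index`` are the indices of the outermost
    *consistent* markers of the maximal locus-containing run of non-refuting
    markers, or ``None`` when a side has no consistent marker before the
    first refuting one.  Extents are measured from the locus outward and are
    0 for an empty side.
    """

    sample_id: str
    flags: np.ndarray  # int8 per marker: 1/0/-1
    left_index: int | None
    right_index: int | None
    left_bp: int
    right_bp: int
    left_cM: float
    right_cM: float
    full_share: bool
    any_share: bool

    @property
    def total_cM(self) -> float:
        return self.left_cM + self.right_cM


def share_interval(
    dosages: Sequence[float] | np.ndarray,
    panel: MarkerPanel,
    sample_id: str = "",
) -> ShareResult:
    """Maximal locus-containing run consistent with the founder haplotype.

    Starting from the two markers flanking the locus, the run is grown
    outward on each side until the first refuting (dosage 0) marker.
    Missing genotypes do not stop the scan but do not count as evidence:
    the reported boundary on each side is the outermost marker with a risk
    allele, and sides whose scan finds no such marker are empty.
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape != (len(panel),):
        raise ValueError(
            f"dosage vector length {d.shape} does not match panel size "
            f"{len(panel)}"
        )
    flags = consistency_flags(d)
    left_adj, right_adj = panel.flank_indices()

    def scan(start: int, step: int) -> int | None:
        outermost = None
        i = start
        while 0 <= i < len(panel):
            f = flags[i]
            if f == 0:
                break
            if f == 1:
                outermost = i
            i += step
        return outermost

    left_index = scan(left_adj, -1)
    right_index = scan(right_adj, +1)
    # A marker exactly at the locus belongs to both sides: if it refutes,
    # both scans stop immediately and the sample shares nothing.
    pos = panel.pos_bp
    g = panel.gpos_cM
    locus_cm = panel.locus_cM
    left_bp = int(panel.locus_bp - pos[left_index]) if left_index is not None else 0
    right_bp = int(pos[right_index] - panel.locus_bp) if right_index is not None else 0
    left_cm = float(locus_cm - g[left_index]) if left_index is not None else 0.0
    right_cm = float(g[right_index] - locus_cm) if right_index is not None else 0.0
    return ShareResult(
        sample_id=sample_id,
        flags=flags,
        left_index=left_index,
        right_index=right_index,
        left_bp=left_bp,
        right_bp=right_bp,
        left_cM=left_cm,
        right_cM=right_cm,
        full_share=bool((flags != 0).all()),
        any_share=left_index is not None or right_index is not None,
    )


@dataclass
class ShareSummary:
    n: int
    n_full: int
    n_any: int

    @property
    def frac_full(self) -> float:
        return self.n_full / self.n

    @property
    def frac_any(self) -> float:
        return self.n_any / self.n


def cohort_share(
    matrix: GenotypeMatrix, panel: MarkerPanel
) -> tuple[list[ShareResult], ShareSummary]:
    """Per-sample sharing results plus full/any sharing fractions."""
    if matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    results = [
        share_interval(row, panel, sample_id=sid)
        for sid, row in zip(matrix.sample_ids, matrix.dosages)
    ]
    summary = ShareSummary(
        n=len(results),
        n_full=sum(r.full_share for r in results),
        n_any=sum(r.any_share for r in results),
    )
    return results, summary


def shares_to_frame(results: list[ShareResult]) -> pd.DataFrame:
    """Tabulate sharing results, sorted by total genetic extent (desc)."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "left_index": [r.left_index for r in results],
            "right_index": [r.right_index for r in results],
            "left_bp": [r.left_bp for r in results],
            "right_bp": [r.right_bp for r in results],
            "left_cM": [r.left_cM for r in results],
            "right_cM": [r.right_cM for r in results],
            "full_share": [r.full_share for r in results],
            "any_share": [r.any_share for r in results],
        }
    )
    df["total_cM"] = df["left_cM"] + df["right_cM"]
    return df.sort_values("total_cM", ascending=False, kind="stable").reset_index(
        drop=True
    )


def consistency_matrix_frame(
    results: list[ShareResult], panel: MarkerPanel
) -> pd.DataFrame:
    """Samples x markers matrix with 1=consistent, 0=inconsistent, .=missing.

    The export used to draw a decay-plot style figure.
    """
    cells = {
        r.sample_id: ["." if f == -1 else str(int(f)) for f in r.flags]
        for r in results
    }
    return pd.DataFrame.from_dict(
        cells, orient="index", columns=panel.marker_ids
    )
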