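"""Readers, writers and carrier classification for the screening pipeline.

File formats
------------
Marker panel TSV
    A header line ``#locus_bp=<int>;build=<label>`` followed by a tab-separated
    table with columns ``marker_id, chrom, pos_bp, risk_allele, other_allele,
    risk_freq, gpos_cM``.  Coordinates are 1-based and build-agnostic (the
    build is recorded as a label only).

Genotypes
    Either a TSV (rows = samples, columns = marker ids, cells 0/1/2/NA) or a
    biallelic VCF with GT fields.  Dosages are always oriented to the
    founder-risk allele: a VCF record whose REF is the panel's *other* allele
    is flipped (dosage := 2 - raw ALT count).

Subjects TSV
    Columns ``sample_id, diagnosis, familial, sex, region, ethnicity, carrier,
    age_onset_y, age_last_y, onset_site, ftd_presentation``.  Missing fields
    stay missing; nothing is imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "MarkerPanel",
    "GenotypeMatrix",
    "Subject",
    "CarrierClass",
    "FormatError",
    "ValidationError",
    "classify_repeat_count",
    "read_marker_panel",
    "write_marker_panel",
    "read_genotypes",
    "write_genotypes",
    "read_subjects",
    "write_subjects",
    "read_repeat_counts",
]

MISSING_CODE = "NA"

#: pathogenic expansion threshold (repeat units, exclusive)
EXPANSION_THRESHOLD = 30
#: wild-type threshold (repeat units, exclusive)
WILD_TYPE_THRESHOLD = 20


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


class CarrierClass(Enum):
    """Classification of a repeat-primed PCR repeat count.

    Counts above 30 repeat units are pathogenic expansions, counts below 20
    are wild-type alleles, and the 20-30 band - which the assay does not
    resolve into either category - is reported as ``INDETERMINATE`` and is
    excluded from carrier counts downstream.
    """

    EXPANDED = "expanded"
    WILD_TYPE = "wild_type"
    INDETERMINATE = "indeterminate"


def classify_repeat_count(count: int) -> CarrierClass:
    """Classify a repeat count into expanded / wild-type / indeterminate.

    Parameters
    ----------
    count
        Number of repeat units measured for the sample's longer allele.
        Must be a non-negative integer.

    Returns
    -------
    CarrierClass
        ``EXPANDED`` for count > 30, ``WILD_TYPE`` for count < 20,
        ``INDETERMINATE`` for the 20-30 band.
    """
    if count < 0 or count != int(count):
        raise ValueError(f"repeat count must be a non-negative integer, got {count!r}")
    if count > EXPANSION_THRESHOLD:
        return CarrierClass.EXPANDED
    if count < WILD_TYPE_THRESHOLD:
        return CarrierClass.WILD_TYPE
    return CarrierClass.INDETERMINATE


_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class Marker:
    """A single biallelic SNP of the founder risk haplotype panel."""

    marker_id: str
    chrom: str
    pos_bp: int
    risk_allele: str
    other_allele: str
    risk_freq: float
    gpos_cM: float

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValidationError(f"{self.marker_id}: pos_bp must be >= 1")
        for al in (self.risk_allele, self.other_allele):
            if al not in _IUPAC:
                raise ValidationError(f"{self.marker_id}: invalid allele {al!r}")
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.marker_id}: risk and other allele identical")
        if not 0.0 <= self.risk_freq <= 1.0:
            raise ValidationError(f"{self.marker_id}: risk_freq outside [0,1]")
        if self.gpos_cM < 0:
            raise ValidationError(f"{self.marker_id}: gpos_cM must be >= 0")


@dataclass
class MarkerPanel:
    """Ordered SNP panel defining the founder risk haplotype around a locus.

    The expansion locus at ``locus_bp`` must lie within the physical span of
    the markers; its genetic position is linearly interpolated in bp between
    the flanking map anchors.
    """

    markers: list[Marker]
    locus_bp: int
    build_label: str = ""

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("panel has no markers")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate marker_id(s): {', '.join(dupes)}")
        pos = [m.pos_bp for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("marker pos_bp must be strictly increasing")
        g = [m.gpos_cM for m in self.markers]
        for i, (a, b) in enumerate(zip(g, g[1:])):
            if b < a:
                raise ValidationError(
                    f"gpos_cM decreases between rows {i + 1} and {i + 2}"
                )
        if not (pos[0] <= self.locus_bp <= pos[-1]):
            raise ValidationError(
                f"locus_bp={self.locus_bp} outside marker span "
                f"[{pos[0]}, {pos[-1]}]"
            )

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def pos_bp(self) -> np.ndarray:
        return np.array([m.pos_bp for m in self.markers], dtype=np.int64)

    @property
    def gpos_cM(self) -> np.ndarray:
        return np.array([m.gpos_cM for m in self.markers], dtype=float)

    @property
    def risk_freq(self) -> np.ndarray:
        return np.array([m.risk_freq for m in self.markers], dtype=float)

    @property
    def locus_cM(self) -> float:
        """Genetic position of the locus, interpolated linearly in bp."""
        return float(np.interp(self.locus_bp, self.pos_bp, self.gpos_cM))

    def flank_indices(self) -> tuple[int, int]:
        """Indices of the markers adjacent to the locus.

        Returns ``(left, right)`` where ``left`` is the last marker with
        ``pos_bp <= locus_bp`` and ``right`` the first with
        ``pos_bp >= locus_bp``; they coincide when a marker sits exactly at
        the locus.
        """
        pos = self.pos_bp
        left = int(np.searchsorted(pos, self.locus_bp, side="right")) - 1
        right = int(np.searchsorted(pos, self.locus_bp, side="left"))
        return left, right


@dataclass
class GenotypeMatrix:
    """Per-sample unphased founder-risk-allele dosages over a panel.

    ``dosages`` is a float array of shape ``(n_samples, n_markers)`` with
    values 0/1/2 and ``nan`` for missing genotypes.
    """

    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sample_ids):
            raise ValidationError("dosage matrix shape does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


_DIAGNOSES = {"ALS", "FTD", "control"}
_SEXES = {"male", "female", "unknown"}
_ONSET_SITES = {"bulbar", "limb"}
_FTD_PRESENTATIONS = {"behavioural", "pnfa", "semantic"}


@dataclass
class Subject:
    """One screened individual with the clinical fields the tables use."""

    sample_id: str
    diagnosis: str
    familial: bool
    sex: str = "unknown"
    region: str = ""
    ethnicity: str = ""
    carrier: bool | None = None  # None = unknown / indeterminate
    age_onset_y: float | None = None
    age_last_y: float | None = None
    onset_site: str | None = None
    ftd_presentation: str | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in _DIAGNOSES:
            raise ValidationError(
                f"{self.sample_id}: unknown diagnosis {self.diagnosis!r}"
            )
        if self.sex not in _SEXES:
            raise ValidationError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.onset_site is not None and self.onset_site not in _ONSET_SITES:
            raise ValidationError(
                f"{self.sample_id}: unknown onset_site {self.onset_site!r}"
            )
        if (
            self.ftd_presentation is not None
            and self.ftd_presentation not in _FTD_PRESENTATIONS
        ):
            raise ValidationError(
                f"{self.sample_id}: unknown ftd_presentation "
                f"{self.ftd_presentation!r}"
            )
        if self.diagnosis == "control" and self.age_onset_y is not None:
            raise ValidationError(
                f"{self.sample_id}: control subjects cannot have an onset age"
            )
        if (
            self.age_onset_y is not None
            and self.age_last_y is not None
            and self.age_onset_y > self.age_last_y
        ):
            raise ValidationError(
                f"{self.sample_id}: age_onset_y {self.age_onset_y} exceeds "
                f"age_last_y {self.age_last_y}"
            )


# ---------------------------------------------------------------------------
# marker panel I/O

def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a marker-panel TSV (see module docstring for the layout)."""
    path = Path(path)
    locus_bp = None
    build = ""
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            for token in line[1:].strip().split(";"):
                if token.startswith("locus_bp="):
                    locus_bp = int(token.split("=", 1)[1])
                elif token.startswith("build="):
                    build = token.split("=", 1)[1]
    if locus_bp is None:
        raise FormatError(f"{path}: missing '#locus_bp=...' header line")
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    required = {
        "marker_id", "chrom", "pos_bp", "risk_allele",
        "other_allele", "risk_freq", "gpos_cM",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("pos_bp", kind="stable")
    markers = [
        Marker(
            marker_id=str(r.marker_id),
            chrom=str(r.chrom),
            pos_bp=int(r.pos_bp),
            risk_allele=str(r.risk_allele),
            other_allele=str(r.other_allele),
            risk_freq=float(r.risk_freq),
            gpos_cM=float(r.gpos_cM),
        )
        for r in df.itertuples()
    ]
    return MarkerPanel(markers=markers, locus_bp=locus_bp, build_label=build)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#locus_bp={panel.locus_bp};build={panel.build_label}\n")
        fh.write(
            "marker_id\tchrom\tpos_bp\trisk_allele\tother_allele"
            "\trisk_freq\tgpos_cM\n"
        )
        for m in panel.markers:
            fh.write(
                f"{m.marker_id}\t{m.chrom}\t{m.pos_bp}\t{m.risk_allele}"
                f"\t{m.other_allele}\t{m.risk_freq:.10g}\t{m.gpos_cM:.10g}\n"
            )


# ---------------------------------------------------------------------------
# genotype I/O

def read_genotypes(path: str | Path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read founder-risk-allele dosages from a TSV or a biallelic VCF.

    VCF genotypes are oriented against the panel: records whose REF/ALT match
    the panel's risk/other alleles contribute ``2 - alt_count`` risk alleles;
    the swapped orientation contributes ``alt_count``.  Panel sites absent
    from the file, and ``./.`` genotypes, become missing.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        return _read_genotypes_vcf(path, panel)
    return _read_genotypes_tsv(path, panel)


def _read_genotypes_tsv(path: Path, panel: MarkerPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing_cols = [m for m in panel.marker_ids if m not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: sample columns do not match panel "
            f"(missing {missing_cols[:5]}{'...' if len(missing_cols) > 5 else ''})"
        )
    extra = [c for c in df.columns if c not in set(panel.marker_ids)]
    if extra:
        raise FormatError(f"{path}: unknown marker columns {extra[:5]}")
    df = df[panel.marker_ids]
    dos = df.replace(MISSING_CODE, np.nan).astype(float).to_numpy()
    return GenotypeMatrix(sample_ids=[str(s) for s in df.index], dosages=dos)


def _read_genotypes_vcf(path: Path, panel: MarkerPanel) -> GenotypeMatrix:
    import pysam

    by_site = {(m.chrom, m.pos_bp): j for j, m in enumerate(panel.markers)}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        dos = np.full((len(samples), len(panel)), np.nan)
        for rec in vf:
            key = (rec.chrom, rec.pos)
            j = by_site.get(key)
            if j is None:
                continue
            m = panel.markers[j]
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(
                    f"{path}: marker {m.marker_id} is not biallelic in VCF"
                )
            ref, alt = rec.ref, alts[0]
            if (ref, alt) == (m.risk_allele, m.other_allele):
                risk_is_ref = True
            elif (ref, alt) == (m.other_allele, m.risk_allele):
                risk_is_ref = False
            else:
                raise FormatError(
                    f"{path}: marker {m.marker_id} alleles {ref}/{alt} match "
                    f"neither orientation of panel "
                    f"{m.risk_allele}/{m.other_allele}"
                )
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = sum(gt)
                dos[i, j] = 2 - alt_count if risk_is_ref else alt_count
    return GenotypeMatrix(sample_ids=samples, dosages=dos)


def write_genotypes(matrix: GenotypeMatrix, panel: MarkerPanel,
                    path: str | Path) -> None:
    """Write a dosage TSV (rows = samples, columns = panel marker ids)."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(panel.marker_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.dosages):
            cells = [
                MISSING_CODE if math.isnan(v) else str(int(v)) for v in row
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# subject I/O

_SUBJECT_COLUMNS = [
    "sample_id", "diagnosis", "familial", "sex", "region", "ethnicity",
    "carrier", "age_onset_y", "age_last_y", "onset_site", "ftd_presentation",
]

_BOOL_TOKENS = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False,
}


def _parse_bool(token: str, *, row: str, col: str) -> bool | None:
    t = token.strip().lower()
    if t in {"", "na", "unknown"}:
        return None
    if t not in _BOOL_TOKENS:
        raise FormatError(f"row {row}: cannot parse {col}={token!r} as boolean")
    return _BOOL_TOKENS[t]


def read_subjects(path: str | Path) -> list[Subject]:
    """Read the subjects TSV into validated :class:`Subject` records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    def opt(v: str) -> str | None:
        return None if v.strip() in {"", MISSING_CODE} else v.strip()

    subjects = []
    for r in df.itertuples():
        sid = str(r.sample_id)
        fam = _parse_bool(r.familial, row=sid, col="familial")
        if fam is None:
            raise FormatError(f"row {sid}: familial flag is required")
        onset = opt(r.age_onset_y)
        last = opt(r.age_last_y)
        subjects.append(
            Subject(
                sample_id=sid,
                diagnosis=r.diagnosis.strip(),
                familial=fam,
                sex=opt(r.sex) or "unknown",
                region=opt(r.region) or "",
                ethnicity=opt(r.ethnicity) or "",
                carrier=_parse_bool(r.carrier, row=sid, col="carrier"),
                age_onset_y=None if onset is None else float(onset),
                age_last_y=None if last is None else float(last),
                onset_site=opt(r.onset_site),
                ftd_presentation=opt(r.ftd_presentation),
            )
        )
    return subjects


def write_subjects(subjects: Iterable[Subject], path: str | Path) -> None:
    def cell(v) -> str:
        if v is None:
            return MISSING_CODE
        if isinstance(v, bool):
            return "1" if v else "0"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(_SUBJECT_COLUMNS) + "\n")
        for s in subjects:
            fh.write(
                "\t".join(
                    cell(getattr(s, c)) for c in _SUBJECT_COLUMNS
                )
                + "\n"
            )


def read_repeat_counts(path: str | Path) -> pd.DataFrame:
    """Read a repeat-count TSV and attach the carrier classification.

    Returns a DataFrame with columns ``sample_id``, ``repeat_count`` and
    ``carrier_class`` (string values of :class:`CarrierClass`).
    """
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "repeat_count"} <= set(df.columns):
        raise FormatError(f"{path}: need columns sample_id, repeat_count")
    df = df.copy()
    df["carrier_class"] = [
        classify_repeat_count(int(c)).value for c in df["repeat_count"]
    ]
    return df
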