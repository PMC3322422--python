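"""Synthetic founder cohorts with known ground truth.

The generator emulates the three data layers the pipeline consumes:

* **Genotypes** — each carrier descends from a single founder chromosome
  carrying the full risk haplotype.  Under the default star genealogy the
  lineage to the founder is ``G`` independent meioses, so the distance from
  the locus to the first recombination on each side is Exponential with rate
  ``G`` per Morgan.  Markers inside the breakpoints keep the founder risk
  allele; markers beyond are redrawn from the background risk-allele
  frequencies, as is the entire partner chromosome.  Unphased dosages are
  the per-site sums, with optional genotyping missingness.
* **Clinical records** — affected carriers draw onset ages from a
  truncated normal (defaults 56.8 y mean, 9.1 y SD); a configurable fraction
  of carriers remain unaffected and are censored at an age drawn from
  ``censor_age_range``.  Sex, site of onset and FTD presentation are drawn
  at configurable group-specific rates.
* **Repeat counts** — carriers draw pathogenic counts (> 30 units),
  non-carriers wild-type counts (< 20 units).

A ``correlated`` genealogy mode routes carriers through a layer of shared
intermediate ancestors, which induces the correlation of lineages that the
star-genealogy age estimator ignores; it exists to demonstrate that bias.

Every generative parameter, the realised carrier count and the true per-side
breakpoints are recorded in a truth dictionary so that estimators can be
scored against the simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import (
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    Subject,
    write_genotypes,
    write_marker_panel,
    write_subjects,
)

__all__ = [
    "SimConfig",
    "StratumSpec",
    "SimulatedCohort",
    "synthetic_panel",
    "simulate_carrier_chromosome",
    "simulate_cohort",
    "censored_exponential_mean",
]


def synthetic_panel(
    n_markers: int = 42,
    chrom: str = "9",
    start_bp: int = 27_000_000,
    span_bp: int = 2_400_000,
    cm_per_mb: float = 1.0,
    risk_freq_range: tuple[float, float] = (0.05, 0.35),
    flank_offset_bp: int = 2_400,
    seed: int | None = None,
) -> MarkerPanel:
    """Build a marker panel flanking an expansion locus at the span midpoint.

    Markers are spread evenly over ``span_bp`` except for the two tag SNPs
    placed ``flank_offset_bp`` either side of the locus, mirroring panels
    whose most associated markers tightly bracket the causal variant.
    Background risk-allele frequencies are drawn uniformly from
    ``risk_freq_range``; the default range keeps the risk haplotype on the
    less common allele at each site, which is what makes unphased
    consistency informative.  The genetic map is linear at ``cm_per_mb``.
    """
    if n_markers < 4:
        raise ValueError("need at least 4 markers")
    rng = np.random.default_rng(seed)
    locus = start_bp + span_bp // 2
    half = (n_markers - 2) // 2
    left = np.linspace(start_bp, locus - 20 * flank_offset_bp, half)
    right = np.linspace(
        locus + 20 * flank_offset_bp, start_bp + span_bp, n_markers - 2 - half
    )
    pos = np.sort(
        np.concatenate(
            [left, [locus - flank_offset_bp, locus + flank_offset_bp], right]
        ).astype(np.int64)
    )
    freqs = rng.uniform(*risk_freq_range, size=n_markers)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    markers = [
        Marker(
            marker_id=f"rs{900000 + i}",
            chrom=chrom,
            pos_bp=int(p),
            risk_allele=alleles[i % 4][0],
            other_allele=alleles[i % 4][1],
            risk_freq=float(f),
            gpos_cM=float((p - start_bp) / 1e6 * cm_per_mb),
        )
        for i, (p, f) in enumerate(zip(pos, freqs))
    ]
    return MarkerPanel(markers=markers, locus_bp=locus, build_label="synthetic")


@dataclass
class StratumSpec:
    """One cohort stratum with its own size and true carrier rate."""

    n: int
    carrier_rate: float
    diagnosis: str = "ALS"
    familial: bool = False
    region: str = "synthetic"
    ethnicity: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("stratum n must be >= 0")
        if not 0 <= self.carrier_rate <= 1:
            raise ValueError("carrier_rate must be in [0, 1]")


@dataclass
class SimConfig:
    """All generative knobs of the synthetic founder cohort.

    Defaults are the study conditions the pipeline is meant to operate
    under: founder age 100 generations, 262 carriers, carrier
    onset ages 56.8 (SD 9.1) years, ~1% of carriers unaffected at
    ascertainment, pathogenic repeat counts above 30 units and wild-type
    counts below 20.
    """

    panel: MarkerPanel
    founder_age_G: float = 100.0
    n_carriers: int = 262
    n_noncarriers: int = 0
    onset_mean_y: float = 56.8
    onset_sd_y: float = 9.1
    noncarrier_onset_mean_y: float = 58.7
    noncarrier_onset_sd_y: float = 12.8
    unaffected_carrier_frac: float = 0.01
    censor_age_range: tuple[float, float] = (40.0, 75.0)
    male_frac_carrier: float = 0.501
    male_frac_noncarrier: float = 0.584
    bulbar_frac_carrier: float = 0.331
    bulbar_frac_noncarrier: float = 0.260
    ftd_presentation_carrier: tuple[float, float, float] = (0.855, 0.089, 0.056)
    ftd_presentation_noncarrier: tuple[float, float, float] = (0.656, 0.158, 0.186)
    repeat_count_dists: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "expanded": (1200.0, 500.0),
            "wild_type": (7.0, 3.0),
        }
    )
    genotyping_missing_rate: float = 0.0
    diagnosis: str = "ALS"
    familial: bool = False
    region: str = "synthetic"
    ethnicity: str = "synthetic"
    strata: list[StratumSpec] | None = None
    genealogy: str = "star"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.founder_age_G <= 0:
            raise ValueError("founder_age_G must be > 0")
        if self.n_carriers < 0 or self.n_noncarriers < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.onset_sd_y <= 0:
            raise ValueError("onset_sd_y must be > 0")
        for r in (
            self.unaffected_carrier_frac,
            self.genotyping_missing_rate,
            self.male_frac_carrier,
            self.male_frac_noncarrier,
            self.bulbar_frac_carrier,
            self.bulbar_frac_noncarrier,
        ):
            if not 0 <= r <= 1:
                raise ValueError("all rates must lie in [0, 1]")
        if self.genealogy not in {"star", "correlated"}:
            raise ValueError("genealogy must be 'star' or 'correlated'")


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, size: int,
    lower: float = 0.0, upper: float = np.inf,
) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_carrier_chromosome(
    panel: MarkerPanel,
    founder_age_G: float,
    rng: np.random.Generator,
    genotyping_missing_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """Simulate one carrier: phased haplotypes, dosages and true breakpoints.

    Returns ``(hap_expansion, hap_partner, dosages, (break_left_M,
    break_right_M))`` where haplotypes are 0/1 risk-allele indicators and
    dosages carry ``nan`` at sites masked by genotyping missingness.
    """
    dos, breaks, haps = _simulate_carriers(
        panel, founder_age_G, 1, rng, genotyping_missing_rate,
        return_haplotypes=True,
    )
    return haps[0][0], haps[1][0], dos[0], (float(breaks[0, 0]), float(breaks[0, 1]))


def _decay_haplotype(
    panel: MarkerPanel,
    breaks: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes eroded outside per-sample (left, right) breaks."""
    n = breaks.shape[0]
    dist = (panel.gpos_cM - panel.locus_cM) / 100.0  # signed Morgans
    left_dist = np.where(dist <= 0, -dist, np.inf)
    right_dist = np.where(dist >= 0, dist, np.inf)
    intact = (left_dist[None, :] <= breaks[:, [0]]) | (
        right_dist[None, :] <= breaks[:, [1]]
    )
    background = rng.random((n, len(panel))) < panel.risk_freq[None, :]
    return np.where(intact, 1, background).astype(np.int8)


def _simulate_carriers(
    panel: MarkerPanel,
    founder_age_G: float,
    n: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    genealogy: str = "star",
    return_haplotypes: bool = False,
):
    """Vectorised carrier simulation; returns dosages, breaks, (haplotypes)."""
    if genealogy == "star":
        breaks = rng.exponential(1.0 / founder_age_G, size=(n, 2))
    else:
        # two-level genealogy: carriers share intermediate ancestors at G/2
        n_anc = max(1, n // 5)
        anc_breaks = rng.exponential(2.0 / founder_age_G, size=(n_anc, 2))
        assign = rng.integers(0, n_anc, size=n)
        own = rng.exponential(2.0 / founder_age_G, size=(n, 2))
        breaks = np.minimum(anc_breaks[assign], own)
    hap_exp = _decay_haplotype(panel, breaks, rng)
    hap_partner = (
        rng.random((n, len(panel))) < panel.risk_freq[None, :]
    ).astype(np.int8)
    dos = (hap_exp + hap_partner).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    if return_haplotypes:
        return dos, breaks, (hap_exp, hap_partner)
    return dos, breaks


def _simulate_noncarriers(
    panel: MarkerPanel, n: int, rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> np.ndarray:
    f = panel.risk_freq[None, :]
    dos = (
        (rng.random((n, len(panel))) < f).astype(float)
        + (rng.random((n, len(panel))) < f)
    )
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return dos


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation produced, plus its ground truth."""

    genotypes: GenotypeMatrix
    subjects: list[Subject]
    repeat_counts: pd.DataFrame
    truth: dict
    panel: MarkerPanel

    def write(self, out_dir: str | Path) -> None:
        """Write panel.tsv, genotypes.tsv, subjects.tsv, repeats.tsv, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_marker_panel(self.panel, out / "panel.tsv")
        write_genotypes(self.genotypes, self.panel, out / "genotypes.tsv")
        write_subjects(self.subjects, out / "subjects.tsv")
        self.repeat_counts.to_csv(out / "repeats.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _draw_repeat_counts(
    rng: np.random.Generator, dist: tuple[float, float], n: int,
    lower: float, upper: float,
) -> np.ndarray:
    mean, sd = dist
    return np.round(
        _truncnorm_draw(rng, mean, sd, n, lower=lower, upper=upper)
    ).astype(int)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate genotypes, clinical records and repeat counts per the config.

    With ``config.strata`` set, each stratum's carrier count is binomial at
    its true rate; otherwise ``n_carriers`` / ``n_noncarriers`` are taken as
    exact counts of a single stratum.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel

    if config.strata is not None:
        strata = config.strata
        carrier_counts = [
            int(rng.binomial(st.n, st.carrier_rate)) for st in strata
        ]
    else:
        total = config.n_carriers + config.n_noncarriers
        strata = [
            StratumSpec(
                n=total,
                carrier_rate=config.n_carriers / total if total else 0.0,
                diagnosis=config.diagnosis,
                familial=config.familial,
                region=config.region,
                ethnicity=config.ethnicity,
            )
        ]
        carrier_counts = [config.n_carriers]

    n_car_total = sum(carrier_counts)
    dosage_blocks: list[np.ndarray] = []
    breaks = np.empty((0, 2))
    if n_car_total:
        car_dos, breaks = _simulate_carriers(
            panel, config.founder_age_G, n_car_total, rng,
            config.genotyping_missing_rate, config.genealogy,
        )
        dosage_blocks.append(car_dos)
    n_non_total = sum(st.n for st in strata) - n_car_total
    if n_non_total:
        dosage_blocks.append(
            _simulate_noncarriers(
                panel, n_non_total, rng, config.genotyping_missing_rate
            )
        )

    subjects: list[Subject] = []
    repeat_rows: list[dict] = []
    car_i = 0
    non_i = 0

    def make_subject(sid: str, st: StratumSpec, is_carrier: bool) -> Subject:
        if is_carrier:
            unaffected = rng.random() < config.unaffected_carrier_frac
            onset_mean, onset_sd = config.onset_mean_y, config.onset_sd_y
            male_p = config.male_frac_carrier
            bulbar_p = config.bulbar_frac_carrier
            pres_p = config.ftd_presentation_carrier
        else:
            unaffected = st.diagnosis == "control"
            onset_mean = config.noncarrier_onset_mean_y
            onset_sd = config.noncarrier_onset_sd_y
            male_p = config.male_frac_noncarrier
            bulbar_p = config.bulbar_frac_noncarrier
            pres_p = config.ftd_presentation_noncarrier
        sex = "male" if rng.random() < male_p else "female"
        if unaffected or st.diagnosis == "control":
            return Subject(
                sample_id=sid, diagnosis="control", familial=st.familial,
                sex=sex, region=st.region, ethnicity=st.ethnicity,
                carrier=is_carrier,
                age_last_y=float(rng.uniform(*config.censor_age_range)),
            )
        onset = float(_truncnorm_draw(rng, onset_mean, onset_sd, 1)[0])
        site = None
        pres = None
        if st.diagnosis == "ALS":
            site = "bulbar" if rng.random() < bulbar_p else "limb"
        elif st.diagnosis == "FTD":
            pres = ["behavioural", "pnfa", "semantic"][
                int(rng.choice(3, p=np.asarray(pres_p) / np.sum(pres_p)))
            ]
        return Subject(
            sample_id=sid, diagnosis=st.diagnosis, familial=st.familial,
            sex=sex, region=st.region, ethnicity=st.ethnicity,
            carrier=is_carrier, age_onset_y=onset,
            age_last_y=onset + float(rng.uniform(0.0, 10.0)),
            onset_site=site, ftd_presentation=pres,
        )

    sample_ids: list[str] = []
    carrier_order: list[bool] = []
    for si, (st, k) in enumerate(zip(strata, carrier_counts)):
        for j in range(st.n):
            is_carrier = j < k
            sid = f"S{si}_{'C' if is_carrier else 'N'}{j:05d}"
            sample_ids.append(sid)
            carrier_order.append(is_carrier)
            subjects.append(make_subject(sid, st, is_carrier))
            if is_carrier:
                car_i += 1
            else:
                non_i += 1

    car_ids = [s for s, c in zip(sample_ids, carrier_order) if c]
    non_ids = [s for s, c in zip(sample_ids, carrier_order) if not c]
    exp_counts = _draw_repeat_counts(
        rng, config.repeat_count_dists["expanded"], len(car_ids),
        lower=31.0, upper=np.inf,
    )
    wt_counts = _draw_repeat_counts(
        rng, config.repeat_count_dists["wild_type"], len(non_ids),
        lower=0.0, upper=19.49,
    )
    repeat_rows = [
        {"sample_id": s, "repeat_count": int(c)}
        for s, c in zip(car_ids + non_ids, np.concatenate([exp_counts, wt_counts]))
    ]

    # dosage rows were generated carriers-first; reorder to sample order
    all_dos = (
        np.vstack(dosage_blocks)
        if dosage_blocks
        else np.empty((0, len(panel)))
    )
    order = np.concatenate(
        [
            np.nonzero(carrier_order)[0],
            np.nonzero(~np.asarray(carrier_order))[0],
        ]
    )
    dos_sorted = np.empty_like(all_dos)
    dos_sorted[order] = all_dos
    matrix = GenotypeMatrix(sample_ids=sample_ids, dosages=dos_sorted)

    truth = {
        "founder_age_G": config.founder_age_G,
        "generation_time_y": 15.0,
        "n_carriers": n_car_total,
        "n_noncarriers": n_non_total,
        "onset_mean_y": config.onset_mean_y,
        "onset_sd_y": config.onset_sd_y,
        "unaffected_carrier_frac": config.unaffected_carrier_frac,
        "censor_age_range": list(config.censor_age_range),
        "genotyping_missing_rate": config.genotyping_missing_rate,
        "genealogy": config.genealogy,
        "seed": config.seed,
        "risk_freq": [m.risk_freq for m in panel.markers],
        "strata": [
            {
                "n": st.n,
                "carrier_rate": st.carrier_rate,
                "realised_carriers": int(k),
                "diagnosis": st.diagnosis,
                "familial": st.familial,
                "region": st.region,
            }
            for st, k in zip(strata, carrier_counts)
        ],
        "carrier_break_M": breaks.tolist(),
    }
    return SimulatedCohort(
        genotypes=matrix,
        subjects=subjects,
        repeat_counts=pd.DataFrame(repeat_rows),
        truth=truth,
        panel=panel,
    )


def censored_exponential_mean(G: float, x_edge: float) -> float:
    """E[min(Exp(G), x_edge)] = (1 - exp(-G x_edge)) / G.

    Closed-form expectation of the one-sided shared genetic length when the
    panel edge lies ``x_edge`` Morgans from the locus; used to calibrate the
    simulator against its own model.
    """
    if G <= 0 or x_edge < 0:
        raise ValueError("G must be > 0 and x_edge >= 0")
    return (1.0 - np.exp(-G * x_edge)) / G
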