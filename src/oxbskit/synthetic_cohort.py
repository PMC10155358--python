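"""Simulation of paired RRBS/oxRRBS per-CpG count data.

The generator emulates the statistical structure the downstream analysis
assumes: every CpG dyad carries a true 5mC level ``m`` and a true 5hmC level
``h`` on the simplex (m >= 0, h >= 0, m + h <= 1).  A plain bisulfite (BS)
library protects both marks, so a read reports C with probability close to
``m + h``; an oxidative bisulfite (oxBS) library first oxidises 5hmC so that
it converts like unmodified cytosine, leaving reads that report C with
probability close to ``m``.  Imperfect chemistry (conversion failure,
over-conversion, incomplete oxidation) perturbs both probabilities.

Counts are binomial given a per-site, per-library coverage drawn from a
negative-binomial depth model (RRBS depth is overdispersed).  Group-level
effects are planted as region-wise shifts of ``m`` or ``h`` in the case
group, optionally coupled to an opposite shift of the other mark to emulate
the anti-correlated 5mC/5hmC remodelling seen in tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genomic_annotation import GeneModel, Transcript

Library = Literal["BS", "oxBS"]


@dataclass(frozen=True)
class ChemistryParams:
    """Conversion-chemistry error rates.

    eps_fail : probability an unmodified C escapes conversion (reads as C).
    eps_over : probability a protected base is over-converted (reads as T).
    eta_ox   : probability oxidation converts a 5hmC in the oxBS library so
               that it subsequently reads as T.  eta_ox = 1 is perfect
               oxidation; eta_ox = 0 makes oxBS identical to BS.
    """

    eps_fail: float = 0.005
    eps_over: float = 0.005
    eta_ox: float = 0.95

    def __post_init__(self) -> None:
        for name in ("eps_fail", "eps_over", "eta_ox"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


PERFECT_CHEMISTRY = ChemistryParams(eps_fail=0.0, eps_over=0.0, eta_ox=1.0)


@dataclass(frozen=True)
class RegionEffect:
    """A planted group-level effect on one mark over a genomic interval.

    ``delta`` shifts the named mark in every case-group sample;
    ``coupling`` applies a simultaneous shift to the *other* mark, which is
    how anti-correlated 5mC/5hmC effects are planted (e.g. delta=+0.3 on
    5mC with coupling=-0.15 lowers 5hmC by 0.15 in the same region).
    Post-shift levels are clipped back to the simplex.
    """

    chrom: str
    start: int
    end: int
    mark: Literal["5mC", "5hmC"]
    delta: float
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.mark not in ("5mC", "5hmC"):
            raise ValueError(f"unknown mark {self.mark!r}")
        if abs(self.delta) > 1 or abs(self.coupling) > 1:
            raise ValueError("|delta| and |coupling| must be <= 1")
        if self.end <= self.start:
            raise ValueError("empty region interval")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def dm(self) -> float:
        return self.delta if self.mark == "5mC" else self.coupling

    @property
    def dh(self) -> float:
        return self.delta if self.mark == "5hmC" else self.coupling


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial sequencing depth: mean depth + dispersion.

    ``dispersion`` is the NB size parameter; variance = mean + mean^2/size.
    mean_depth = 0 degenerates to all-zero coverage.
    """

    mean_depth: float = 30.0
    dispersion: float = 5.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean_depth <= 0:
            return np.zeros(n, dtype=np.int64)
        p = self.dispersion / (self.dispersion + self.mean_depth)
        return rng.negative_binomial(self.dispersion, p, size=n)


@dataclass(frozen=True)
class BetaMixture:
    """Mixture of Beta components for baseline methylation levels.

    components: (weight, a, b) triples.  Weights are normalised.
    """

    components: tuple[tuple[float, float, float], ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.array([c[0] for c in self.components], dtype=float)
        w /= w.sum()
        which = rng.choice(len(self.components), size=n, p=w)
        out = np.empty(n)
        for i, (_, a, b) in enumerate(self.components):
            mask = which == i
            out[mask] = rng.beta(a, b, size=mask.sum())
        return out


# Bimodal 5mC baseline: a high, gene-body-like component and a low,
# promoter-like component.  5hmC baseline is low and unimodal, as in
# somatic tissue.
DEFAULT_BASELINE_M = BetaMixture(((0.55, 6.0, 2.0), (0.45, 1.5, 8.0)))
DEFAULT_BASELINE_H = BetaMixture(((1.0, 1.5, 20.0),))


@dataclass
class TruthSpec:
    """Full description of a synthetic cohort.

    group_labels maps each sample (in order) to "case" or "control";
    sample ids are generated as s01, s02, ...  ``sample_effect_sd``
    optionally adds per-(sample, region) Gaussian deviations to both marks
    in every listed region — biological between-sample variability; default
    off so planted effects are homogeneous across case samples.
    """

    cpg_map: pd.DataFrame
    group_labels: Sequence[str]
    regions: list[RegionEffect] = field(default_factory=list)
    baseline_m: BetaMixture | float = DEFAULT_BASELINE_M
    baseline_h: BetaMixture | float = DEFAULT_BASELINE_H
    coverage: CoverageModel = CoverageModel()
    chemistry: ChemistryParams = ChemistryParams()
    sample_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        pos = self.cpg_map.groupby("chrom", sort=False)["pos"]
        if not pos.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
            raise ValueError("positions must be strictly increasing per chromosome")
        for g in self.group_labels:
            if g not in ("case", "control"):
                raise ValueError(f"group label {g!r} not in {{case, control}}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(len(self.group_labels))]


def expected_read_probability(
    m, h, library: Library, chem: ChemistryParams
) -> np.ndarray | float:
    """Probability a read reports C at a CpG with true levels (m, h).

    BS protects 5mC and 5hmC alike; oxBS additionally converts the oxidised
    fraction eta_ox of 5hmC.  Conversion failure (eps_fail) adds false C
    calls from the unmodified fraction and over-conversion (eps_over)
    removes C calls from the protected fraction.
    """
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(m < 0) or np.any(h < 0) or np.any(m + h > 1 + 1e-12):
        raise ValueError("(m, h) must lie on the simplex m, h >= 0, m + h <= 1")
    protected_ox = 1.0 - chem.eps_over
    if library == "BS":
        p = (m + h) * protected_ox + (1.0 - m - h) * chem.eps_fail
    elif library == "oxBS":
        p = (
            m * protected_ox
            + h * (1.0 - chem.eta_ox) * protected_ox
            + (1.0 - m - h) * chem.eps_fail
        )
    else:
        raise ValueError(f"unknown library {library!r}")
    return np.clip(p, 0.0, 1.0)


def simulate_reference(
    n_chromosomes: int,
    cpgs_per_chromosome: int,
    spacing: int | tuple[int, int] | str = "clustered",
    seed: int = 0,
    chrom_offset: int = 10_000,
) -> tuple[pd.DataFrame, GeneModel]:
    """Generate a CpG map plus a minimal transcript model.

    ``spacing`` is a fixed inter-CpG distance, a (lo, hi) range sampled
    uniformly per gap, or ``"clustered"``: mostly short gaps (20-120 bp)
    with occasional long ones (500-3000 bp), emulating the island-like
    CpG clustering of reduced-representation libraries.  Each chromosome
    carries two transcripts (one per strand) spanning interior CpGs, so
    that every annotation category (promoter, exon, TTS, intron,
    intergenic) is realisable.
    """
    if n_chromosomes < 1 or cpgs_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one CpG")
    rng = np.random.default_rng(seed)
    rows = []
    transcripts = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        if spacing == "clustered":
            long = rng.random(cpgs_per_chromosome) < 0.12
            gaps = np.where(
                long,
                rng.integers(500, 3001, size=cpgs_per_chromosome),
                rng.integers(20, 121, size=cpgs_per_chromosome),
            )
        elif isinstance(spacing, (tuple, list)):
            gaps = rng.integers(spacing[0], spacing[1] + 1, size=cpgs_per_chromosome)
        else:
            gaps = np.full(cpgs_per_chromosome, int(spacing))
        pos = chrom_offset + np.cumsum(gaps)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+"}))
        span = int(pos[-1] - pos[0])
        if span >= 20:
            for frac_lo, frac_hi, strand, tag in (
                (0.10, 0.42, "+", "a"),
                (0.58, 0.90, "-", "b"),
            ):
                g_start = int(pos[0] + frac_lo * span)
                g_end = int(pos[0] + frac_hi * span)
                third = max((g_end - g_start) // 3, 1)
                exons = (
                    (g_start, min(g_start + third // 2, g_end)),
                    (
                        min(g_start + third, g_end - 1),
                        min(g_start + third + third // 2, g_end),
                    ),
                    (max(g_end - third // 2, g_start), g_end),
                )
                exons = tuple((s, e) for s, e in exons if s < e)
                transcripts.append(
                    Transcript(chrom, g_start, g_end, strand, exons, f"{chrom}_{tag}")
                )
    cpg_map = pd.concat(rows, ignore_index=True)
    return cpg_map, GeneModel(transcripts=transcripts)


def _site_region_index(cpg_map: pd.DataFrame, regions: Sequence[RegionEffect]):
    """For each region, a boolean mask of CpGs it covers."""
    chrom = cpg_map["chrom"].to_numpy()
    pos = cpg_map["pos"].to_numpy()
    return [
        (chrom == r.chrom) & (pos >= r.start) & (pos < r.end) for r in regions
    ]


def _clip_simplex(m: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 5mC has priority: h absorbs any simplex excess.
    m = np.clip(m, 0.0, 1.0)
    h = np.clip(h, 0.0, 1.0 - m)
    return m, h


def true_levels(truth: TruthSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample true (m, h) matrices of shape (n_samples, n_sites).

    Returns (m_base, h_base, M, H) where the matrices include planted
    region effects and, when enabled, per-(sample, region) heterogeneity.
    Uses its own substream of the TruthSpec seed so that count simulation
    remains reproducible independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0]))
    n_sites = len(truth.cpg_map)
    n_samples = len(truth.group_labels)
    for base in (truth.baseline_m, truth.baseline_h):
        if isinstance(base, float) and not (0 <= base <= 1):
            raise ValueError("fixed baseline outside [0, 1]")
    m0 = (
        np.full(n_sites, truth.baseline_m)
        if isinstance(truth.baseline_m, (int, float))
        else truth.baseline_m.sample(rng, n_sites)
    )
    h0 = (
        np.full(n_sites, truth.baseline_h)
        if isinstance(truth.baseline_h, (int, float))
        else truth.baseline_h.sample(rng, n_sites)
    )
    m0, h0 = _clip_simplex(m0, h0)
    masks = _site_region_index(truth.cpg_map, truth.regions)
    M = np.tile(m0, (n_samples, 1))
    H = np.tile(h0, (n_samples, 1))
    for mask, reg in zip(masks, truth.regions):
        for si, group in enumerate(truth.group_labels):
            dm = reg.dm if group == "case" else 0.0
            dh = reg.dh if group == "case" else 0.0
            if truth.sample_effect_sd > 0:
                dm += rng.normal(0.0, truth.sample_effect_sd)
                dh += rng.normal(0.0, truth.sample_effect_sd)
            if dm or dh:
                M[si, mask] += dm
                H[si, mask] += dh
    for si in range(n_samples):
        M[si], H[si] = _clip_simplex(M[si], H[si])
    return m0, h0, M, H


def simulate_counts(truth: TruthSpec) -> dict[str, dict[str, pd.DataFrame]]:
    """Simulate paired per-CpG call tables for every sample.

    Returns {sample_id: {"bs": table, "ox": table}} with methratio-style
    columns (chrom, pos, strand, context, ratio, c_count, ct_count); pos is
    the internal 0-based coordinate.  Sites with zero coverage in a library
    are omitted from that library's table.  Fully deterministic for a fixed
    TruthSpec (including its seed).
    """
    _, _, M, H = true_levels(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    cpg = truth.cpg_map
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for si, sample in enumerate(truth.sample_ids):
        tables = {}
        for lib_key, lib in (("bs", "BS"), ("ox", "oxBS")):
            cov = truth.coverage.draw(rng, len(cpg))
            p = expected_read_probability(M[si], H[si], lib, truth.chemistry)
            c = rng.binomial(cov, p)
            keep = cov > 0
            with np.errstate(invalid="ignore"):
                ratio = np.where(keep, c / np.maximum(cov, 1), np.nan)
            tables[lib_key] = pd.DataFrame(
                {
                    "chrom": cpg["chrom"].to_numpy()[keep],
                    "pos": cpg["pos"].to_numpy()[keep],
                    "strand": "+",
                    "context": "CG",
                    "ratio": ratio[keep],
                    "c_count": c[keep],
                    "ct_count": cov[keep],
                }
            )
        out[sample] = tables
    return out


def make_cohort_truth(
    n_per_group: int,
    cpg_map: pd.DataFrame,
    regions: Sequence[RegionEffect] = (),
    **kwargs,
) -> TruthSpec:
    """Convenience constructor: n controls followed by n cases."""
    labels = ["control"] * n_per_group + ["case"] * n_per_group
    return TruthSpec(
        cpg_map=cpg_map, group_labels=labels, regions=list(regions), **kwargs
    )


def truth_regions_to_bed(regions: Sequence[RegionEffect], path: str) -> None:
    """Write planted effects as BED6+ (0-based half-open) for audit."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmark\tdelta\tcoupling\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.mark}\t{r.delta}\t{r.coupling}\n"
            )
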