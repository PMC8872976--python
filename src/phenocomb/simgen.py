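"""Synthetic genotype panels and correlated binary diagnostic components.

Binary diagnostic endorsements (a cardinal-symptom item plus five add-on
components, and one "external cohort" trait) are generated under a
multivariate liability-threshold model: each trait's liability is the sum of
a polygenic score built from shared per-SNP effect vectors and a correlated
environmental deviate, and the binary indicator is 1 for individuals in the
top ``prevalence`` fraction of realized liability.

Per-SNP genetic effects are drawn once per seed and shared between the
main cohort and any external cohort simulated under the same seed, so the
true genetic correlation between cohort traits is exactly the architecture's
``genetic_corr`` entry — a known ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "ComponentArchitecture",
    "ComponentTable",
    "COMPONENT_NAMES",
    "INTERNAL_TRAITS",
    "default_architecture",
    "simulate_genotypes",
    "simulate_components",
    "simulate_external_sumstats",
    "standardize_dosages",
]

#: canonical order of the five add-on components
COMPONENT_NAMES = ("recurrence", "symptoms5", "duration", "impairment", "persistence")

#: traits observed in the main cohort's component table
INTERNAL_TRAITS = ("cardinal",) + COMPONENT_NAMES

# spawn keys for the independent random streams derived from one seed;
# _SK_EFFECTS is deliberately shared by simulate_components and
# simulate_external_sumstats so both cohorts see the same effect vectors.
_SK_EFFECTS = 0
_SK_ENV = 1
_SK_EXCL = 2
_SK_MISS = 3
_SK_EXT_GENO = 10
_SK_EXT_ENV = 11


class SimulationError(ValueError):
    """Invalid simulation parameters."""


def _rng(seed: int, spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(spawn_key,)))


@dataclass
class GenotypePanel:
    """Dosage matrix (n individuals x m SNPs, values 0/1/2) with a SNP map.

    ``freq`` stores the generating allele frequency of the counted (a1)
    allele; ``ld_block``/``ld_copy_prob`` record the block-LD structure (if
    any) so an external cohort can be drawn with the same LD.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freq: np.ndarray
    individual_ids: np.ndarray = None  # type: ignore[assignment]
    ld_block: Optional[np.ndarray] = None
    ld_copy_prob: float = 0.0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.individual_ids is None:
            self.individual_ids = np.array(
                [f"I{i:06d}" for i in range(self.dosages.shape[0])]
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, m = self.dosages.shape
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise SimulationError("dosages must be in {0,1,2} with no missing values")
        if len(np.unique(self.snp_ids)) != m:
            raise SimulationError("snp_ids must be unique")
        if np.any((self.freq <= 0) | (self.freq >= 1)):
            raise SimulationError("freq must lie in (0,1)")
        for c in np.unique(self.chrom):
            b = self.bp[self.chrom == c]
            if np.any(np.diff(b) <= 0):
                raise SimulationError(f"bp not strictly increasing on chromosome {c}")

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to SNP (column) mask or index array."""
        return GenotypePanel(
            dosages=self.dosages[:, keep],
            snp_ids=self.snp_ids[keep],
            chrom=self.chrom[keep],
            bp=self.bp[keep],
            a1=self.a1[keep],
            a2=self.a2[keep],
            freq=self.freq[keep],
            individual_ids=self.individual_ids,
            ld_block=None if self.ld_block is None else self.ld_block[keep],
            ld_copy_prob=self.ld_copy_prob,
        )


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize a dosage matrix by sample mean and SD.

    Raises on monomorphic columns: the caller decides how to filter them.
    """
    X = np.asarray(dosages, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise SimulationError("monomorphic SNP: zero-variance column")
    return (X - mu) / sd


def _check_corr(name: str, c: np.ndarray, k: int) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64)
    if c.shape != (k, k):
        raise SimulationError(f"{name} must be {k}x{k}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise SimulationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise SimulationError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise SimulationError(f"{name} must be positive semi-definite")
    return c


def _psd_factor(c: np.ndarray) -> np.ndarray:
    """Lower-triangular-like factor L with L @ L.T == c (eigh fallback for PSD)."""
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(c)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


@dataclass(frozen=True)
class ComponentArchitecture:
    """Liability-scale generative model for correlated binary traits.

    ``h2`` is the per-trait liability heritability; total liability variance
    is 1 by construction (h2-weighted genetic plus (1-h2)-weighted
    environmental correlation structure).
    """

    traits: tuple
    h2: np.ndarray
    genetic_corr: np.ndarray
    env_corr: np.ndarray
    prevalence: np.ndarray
    exclusion_rate: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.traits)
        object.__setattr__(self, "h2", np.asarray(self.h2, dtype=np.float64))
        object.__setattr__(self, "prevalence", np.asarray(self.prevalence, dtype=np.float64))
        if len(set(self.traits)) != k:
            raise SimulationError("trait labels must be unique")
        if self.h2.shape != (k,) or np.any((self.h2 < 0) | (self.h2 > 1)):
            raise SimulationError("h2 must be per-trait values in [0,1]")
        if self.prevalence.shape != (k,) or np.any(
            (self.prevalence <= 0) | (self.prevalence > 1)
        ):
            raise SimulationError("prevalence must be per-trait values in (0,1]")
        if not 0 <= self.exclusion_rate < 1:
            raise SimulationError("exclusion_rate must be in [0,1)")
        object.__setattr__(
            self, "genetic_corr", _check_corr("genetic_corr", self.genetic_corr, k)
        )
        object.__setattr__(self, "env_corr", _check_corr("env_corr", self.env_corr, k))

    def index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise SimulationError(f"unknown trait label: {trait!r}") from None

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def default_architecture(
    *,
    h2: Optional[Sequence[float]] = None,
    genetic_corr_internal: float = 0.9,
    genetic_corr_external: float = 0.75,
    env_corr_internal: float = 0.5,
    prevalence: Optional[Sequence[float]] = None,
    exclusion_rate: float = 0.0245,
) -> ComponentArchitecture:
    """Seven-trait architecture: cardinal + five components + external trait.

    Defaults emulate a web-questionnaire depression study: a common cardinal
    item (~56% endorsement), add-on components endorsed by 30-45% of the
    sample, liability h2 between 0.10 and 0.16, strong genetic sharing among
    components and rg ~0.75 with an externally measured depression trait.
    """
    traits = INTERNAL_TRAITS + ("external_md",)
    k = len(traits)
    if h2 is None:
        h2 = [0.15, 0.12, 0.16, 0.10, 0.13, 0.12, 0.15]
    if prevalence is None:
        prevalence = [0.56, 0.35, 0.40, 0.30, 0.45, 0.40, 0.30]
    g = np.full((k, k), genetic_corr_internal)
    g[-1, :] = g[:, -1] = genetic_corr_external
    np.fill_diagonal(g, 1.0)
    e = np.full((k, k), env_corr_internal)
    e[-1, :] = e[:, -1] = 0.0
    np.fill_diagonal(e, 1.0)
    return ComponentArchitecture(
        traits=traits,
        h2=np.asarray(h2),
        genetic_corr=g,
        env_corr=e,
        prevalence=np.asarray(prevalence),
        exclusion_rate=exclusion_rate,
    )


@dataclass
class ComponentTable:
    """Per-individual binary endorsements; NaN encodes a missing response."""

    individual_ids: np.ndarray
    values: pd.DataFrame  # columns = INTERNAL_TRAITS, float with NaN
    excluded: np.ndarray

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def validate(self, panel: Optional[GenotypePanel] = None) -> None:
        if list(self.values.columns) != list(INTERNAL_TRAITS):
            raise SimulationError(f"component columns must be {INTERNAL_TRAITS}")
        vals = self.values.to_numpy()
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise SimulationError("component values must be 0, 1 or missing")
        if panel is not None and not np.array_equal(
            self.individual_ids, panel.individual_ids
        ):
            raise SimulationError("component table individuals must match the panel")


def simulate_genotypes(
    n: int,
    m: int,
    maf_bounds: Sequence[float] = (0.05, 0.5),
    n_chrom: int = 10,
    seed: int = 0,
    *,
    bp_spacing: int = 150_000,
    ld_block_size: int = 1,
    ld_copy_prob: float = 0.9,
) -> GenotypePanel:
    """Draw an n x m dosage panel, HWE binomial(2, p) per SNP.

    Allele frequencies are uniform on ``maf_bounds``; base-pair positions sit
    on a regular grid per chromosome. With ``ld_block_size > 1`` adjacent
    SNPs form blocks (sizes cycling 1..ld_block_size within a chromosome)
    whose members copy a latent block genotype with probability
    ``ld_copy_prob``, giving pairwise correlation ``ld_copy_prob**2`` and
    hence non-degenerate LD scores.
    """
    if n < 2 or m < 2:
        raise SimulationError("need n >= 2 individuals and m >= 2 SNPs")
    lo, hi = float(maf_bounds[0]), float(maf_bounds[1])
    if not (0 < lo <= hi <= 0.5):
        raise SimulationError("maf_bounds must satisfy 0 < lo <= hi <= 0.5")
    if not 1 <= n_chrom <= m:
        raise SimulationError("n_chrom must be in [1, m]")

    rng = np.random.default_rng(seed)
    chrom_sizes = [len(ix) for ix in np.array_split(np.arange(m), n_chrom)]
    chrom = np.repeat(np.arange(1, n_chrom + 1), chrom_sizes)
    bp = np.concatenate([(np.arange(s) + 1) * bp_spacing for s in chrom_sizes])

    # LD blocks never span a chromosome boundary
    ld_block = None
    if ld_block_size > 1:
        ld_block = np.empty(m, dtype=np.int64)
        nxt, i = 0, 0
        for s in chrom_sizes:
            left = s
            size_cycle = 1
            while left > 0:
                b = min(size_cycle, left)
                ld_block[i : i + b] = nxt
                nxt += 1
                i += b
                left -= b
                size_cycle = size_cycle % ld_block_size + 1

    freq = rng.uniform(lo, hi, size=m)
    if ld_block is not None:
        # all SNPs of a block share the block frequency so marginals are exact
        for b in np.unique(ld_block):
            freq[ld_block == b] = freq[np.argmax(ld_block == b)]

    dosages = _draw_dosages(rng, n, freq, ld_block, ld_copy_prob if ld_block is not None else 0.0)
    return GenotypePanel(
        dosages=dosages,
        snp_ids=np.array([f"snp{j:06d}" for j in range(m)]),
        chrom=chrom,
        bp=bp,
        a1=np.full(m, "A"),
        a2=np.full(m, "G"),
        freq=freq,
        ld_block=ld_block,
        ld_copy_prob=ld_copy_prob if ld_block is not None else 0.0,
    )


def _draw_dosages(
    rng: np.random.Generator,
    n: int,
    freq: np.ndarray,
    ld_block: Optional[np.ndarray],
    ld_copy_prob: float,
) -> np.ndarray:
    m = freq.size
    own = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    if ld_block is None or ld_copy_prob <= 0:
        return own
    blocks, block_of = np.unique(ld_block, return_inverse=True)
    base_freq = np.array([freq[ld_block == b][0] for b in blocks])
    base = rng.binomial(2, base_freq, size=(n, blocks.size)).astype(np.int8)
    copy = rng.random((n, m)) < ld_copy_prob
    return np.where(copy, base[:, block_of], own)


def draw_effects(arch: ComponentArchitecture, m: int, seed: int) -> np.ndarray:
    """Per-SNP effect matrix (m x traits) with cross-trait correlation
    ``genetic_corr``; deterministic given (arch, m, seed) and shared between
    the main and external cohorts simulated under the same seed."""
    rng = _rng(seed, _SK_EFFECTS)
    U = rng.standard_normal((m, arch.n_traits))
    return U @ _psd_factor(arch.genetic_corr).T


def _threshold_top_k(liab: np.ndarray, prevalence: float) -> np.ndarray:
    """Indicator = 1 for the top round(n*K) liabilities (realized-quantile
    thresholding: sample prevalence is exact by construction)."""
    n = liab.size
    k = int(round(n * prevalence))
    if k >= n:
        return np.ones(n, dtype=np.int8)
    out = np.zeros(n, dtype=np.int8)
    if k > 0:
        # stable order so ties break deterministically
        order = np.argsort(-liab, kind="stable")
        out[order[:k]] = 1
    return out


def _liabilities(
    Xs: np.ndarray, B: np.ndarray, arch: ComponentArchitecture, env_rng: np.random.Generator
) -> np.ndarray:
    n, m = Xs.shape
    scale = np.sqrt(arch.h2 / m)
    genetic = Xs @ (B * scale)
    E = env_rng.standard_normal((n, arch.n_traits)) @ _psd_factor(arch.env_corr).T
    return genetic + E * np.sqrt(1.0 - arch.h2)


def simulate_components(
    panel: GenotypePanel,
    arch: ComponentArchitecture,
    seed: int = 0,
    *,
    missing_rate: float = 0.0,
) -> ComponentTable:
    """Generate the main cohort's binary endorsements under the architecture.

    Liabilities combine a polygenic score on the standardized panel with
    correlated environmental noise; indicators are thresholded at the
    realized prevalence quantile. ``missing_rate`` masks component cells
    uniformly at random (a knob standing in for questionnaire skip logic,
    which is not modelled explicitly).
    """
    for t in INTERNAL_TRAITS:
        arch.index(t)
    B = draw_effects(arch, panel.m, seed)
    Xs = standardize_dosages(panel.dosages)
    liab = _liabilities(Xs, B, arch, _rng(seed, _SK_ENV))

    cols = {}
    for t in INTERNAL_TRAITS:
        j = arch.index(t)
        cols[t] = _threshold_top_k(liab[:, j], arch.prevalence[j]).astype(np.float64)
    values = pd.DataFrame(cols, columns=list(INTERNAL_TRAITS))

    if missing_rate > 0:
        miss = _rng(seed, _SK_MISS).random(values.shape) < missing_rate
        values = values.mask(miss)

    excluded = _rng(seed, _SK_EXCL).random(panel.n) < arch.exclusion_rate
    table = ComponentTable(
        individual_ids=panel.individual_ids.copy(), values=values, excluded=excluded
    )
    table.validate(panel)
    return table


def simulate_external_sumstats(
    panel_template: GenotypePanel,
    arch: ComponentArchitecture,
    trait: str,
    n_external: int,
    seed: int = 0,
):
    """GWAS summary statistics from an independent cohort sharing the SNP map
    and (critically) the per-SNP effect vectors of the main cohort.

    A fresh cohort of ``n_external`` individuals is drawn on the template's
    frequencies and LD structure, the named trait's binary indicator is
    generated, and a per-SNP linear-regression GWAS of the indicator on
    dosage is run. Returns an :class:`~phenocomb.ldscore.AssocSummary`.
    """
    from .ldscore import AssocSummary, linear_gwas

    if n_external < 100:
        raise SimulationError("n_external must be >= 100")
    j = arch.index(trait)
    B = draw_effects(arch, panel_template.m, seed)

    geno_rng = _rng(seed, _SK_EXT_GENO)
    dos = _draw_dosages(
        geno_rng, n_external, panel_template.freq, panel_template.ld_block,
        panel_template.ld_copy_prob,
    )
    Xs = standardize_dosages(dos)
    g = Xs @ (B[:, j] * np.sqrt(arch.h2[j] / panel_template.m))
    e = _rng(seed, _SK_EXT_ENV).standard_normal(n_external)
    liab = g + e * np.sqrt(1.0 - arch.h2[j])
    y = _threshold_top_k(liab, arch.prevalence[j]).astype(np.float64)

    z, n_eff = linear_gwas(dos, y - y.mean())
    return AssocSummary(
        snp_ids=panel_template.snp_ids.copy(),
        a1=panel_template.a1.copy(),
        a2=panel_template.a2.copy(),
        z=z,
        n_eff=n_eff,
    )
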