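"""Liability-scale SNP heritability from individual-level data.

The estimator is phenotype-correlation-genotype-correlation (PCGC)
regression in its random-ascertainment reduction: because population
prevalence is taken to equal the sample prevalence, PCGC coincides with
Haseman-Elston regression of pairwise phenotype products y_i*y_j on genomic
relatedness g_ij over all i<j pairs (with intercept), followed by the
standard observed-to-liability conversion

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)),

where K is the population prevalence, P the case proportion and z the
standard-normal density at the threshold Phi^{-1}(1-K). Standard errors come
from a delete-one-block jackknife over individuals (200 contiguous blocks of
a seeded shuffle), which also supplies the per-block replicates the
comparison machinery needs for difference tests under sample overlap.

The phenotype is residualized on covariates and standardized once on the
full sample; jackknife replicates resample only the pairwise quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .phenogrid import CASE, CONTROL, CaseControlAssignment, PhenotypeError
from .simgen import GenotypePanel, standardize_dosages

__all__ = [
    "GRM",
    "HeritabilityEstimate",
    "exclude_region",
    "compute_grm",
    "residualize",
    "conversion_factor",
    "pcgc_h2",
    "he_regression",
]

#: MHC analog used by default when excluding the long-range LD region
MHC_CHROM = 6
MHC_START_BP = 28_866_528
MHC_END_BP = 33_775_446


class EstimationError(ValueError):
    """Estimation impossible on the given inputs."""


@dataclass
class GRM:
    """Genomic relationship matrix (1/m) X_s X_s^T on standardized dosages."""

    values: np.ndarray
    n_snps_used: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class HeritabilityEstimate:
    h2_observed: float
    h2_liability: float
    se_liability: float
    K: float
    P: float
    n_cases: int
    n_controls: int
    se_observed: float = float("nan")
    block_replicates: Optional[np.ndarray] = None  # liability scale, per block

    @property
    def p_value(self) -> float:
        if self.se_liability == 0:
            return 1.0 if self.h2_liability == 0 else 0.0
        return 2.0 * stats.norm.sf(abs(self.h2_liability) / self.se_liability)


def exclude_region(
    panel: GenotypePanel,
    chrom: int = MHC_CHROM,
    start_bp: int = MHC_START_BP,
    end_bp: int = MHC_END_BP,
):
    """Drop SNPs on ``chrom`` with start_bp <= bp <= end_bp (closed interval).

    Returns ``(panel, n_removed)``.
    """
    if start_bp > end_bp:
        raise EstimationError("start_bp must be <= end_bp")
    drop = (panel.chrom == chrom) & (panel.bp >= start_bp) & (panel.bp <= end_bp)
    n_removed = int(drop.sum())
    if n_removed == 0:
        return panel, 0
    return panel.subset_snps(~drop), n_removed


def compute_grm(panel: GenotypePanel) -> GRM:
    """GRM from column-standardized dosages; errors on monomorphic SNPs."""
    if panel.m < 2:
        raise EstimationError("need at least 2 SNPs for a GRM")
    Xs = standardize_dosages(panel.dosages)
    values = (Xs @ Xs.T) / panel.m
    return GRM(values=values, n_snps_used=panel.m)


def residualize(y: np.ndarray, covariates: Optional[np.ndarray] = None) -> np.ndarray:
    """OLS residuals of y on covariates plus an intercept.

    With no covariates this is mean-centering. Raises on rank deficiency.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return y - y.mean()
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def conversion_factor(K: float, P: float) -> float:
    """Observed-scale to liability-scale multiplier for a binary trait.

    Reduces to K(1-K)/z^2 when the case proportion equals the prevalence.
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise EstimationError("K and P must lie strictly in (0,1)")
    z = stats.norm.pdf(stats.norm.isf(K))
    return (K * (1 - K)) ** 2 / (z**2 * P * (1 - P))


def _blocks_from_seed(n: int, n_blocks: int, seed: int) -> List[np.ndarray]:
    if n_blocks < 2 or n_blocks > n:
        raise EstimationError("n_blocks must be in [2, axis length]")
    perm = np.random.default_rng(seed).permutation(n)
    return [b for b in np.array_split(perm, n_blocks)]


def he_regression(G: np.ndarray, y: np.ndarray) -> float:
    """Slope of OLS (with intercept) of y_i y_j on g_ij over all i<j pairs.

    Computed from closed-form sufficient statistics, never materializing the
    pair list.
    """
    stats_ = _PairStats(G, y)
    return stats_.slope(())


class _PairStats:
    """Sufficient statistics for the pairwise HE regression, supporting
    O(|B|^2) leave-one-block-out updates."""

    def __init__(self, G: np.ndarray, y: np.ndarray):
        G = np.asarray(G, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.G = G
        self.y = y
        self.n = y.size
        self.diag = np.diag(G).copy()
        self.rowsum = G.sum(axis=1)
        G2 = G * G
        self.rowsum2 = G2.sum(axis=1)
        self.v = G @ y  # row inner products with y
        self.tot_A = float(self.rowsum.sum())  # sum over all ordered entries
        self.tot_Q = float(self.rowsum2.sum())
        self.tot_diag = float(self.diag.sum())
        self.tot_diag2 = float((self.diag**2).sum())
        self.tot_yGy = float(y @ self.v)
        self.tot_dyy = float((self.diag * y * y).sum())
        self.tot_sy = float(y.sum())
        self.tot_syy = float((y * y).sum())

    def slope(self, block: Sequence[int]) -> float:
        """HE slope after deleting the individuals in ``block``."""
        B = np.asarray(block, dtype=np.intp)
        if B.size:
            GBB = self.G[np.ix_(B, B)]
            yB = self.y[B]
            A = self.tot_A - 2 * self.rowsum[B].sum() + GBB.sum()
            Q = self.tot_Q - 2 * self.rowsum2[B].sum() + (GBB * GBB).sum()
            d = self.tot_diag - self.diag[B].sum()
            d2 = self.tot_diag2 - (self.diag[B] ** 2).sum()
            yGy = self.tot_yGy - 2 * (yB * self.v[B]).sum() + yB @ GBB @ yB
            dyy = self.tot_dyy - (self.diag[B] * yB * yB).sum()
            sy = self.tot_sy - yB.sum()
            syy = self.tot_syy - (yB * yB).sum()
            nk = self.n - B.size
        else:
            A, Q, d, d2 = self.tot_A, self.tot_Q, self.tot_diag, self.tot_diag2
            yGy, dyy, sy, syy = self.tot_yGy, self.tot_dyy, self.tot_sy, self.tot_syy
            nk = self.n
        n_pairs = nk * (nk - 1) / 2.0
        if n_pairs < 2:
            raise EstimationError("too few individuals for the pair regression")
        Sg = (A - d) / 2.0
        Sgg = (Q - d2) / 2.0
        Sgy = (yGy - dyy) / 2.0
        Sy = (sy * sy - syy) / 2.0
        denom = Sgg - Sg * Sg / n_pairs
        if denom <= 0:
            raise EstimationError("GRM off-diagonal variance is zero")
        return (Sgy - Sg * Sy / n_pairs) / denom


def _jackknife_se(replicates: np.ndarray) -> float:
    B = replicates.size
    return float(np.sqrt((B - 1) / B * ((replicates - replicates.mean()) ** 2).sum()))


def pcgc_h2(
    assignment: CaseControlAssignment,
    grm: GRM,
    covariates: Optional[np.ndarray] = None,
    K: Optional[float] = None,
    *,
    n_blocks: int = 200,
    seed: int = 0,
    blocks: Optional[Sequence[np.ndarray]] = None,
) -> HeritabilityEstimate:
    """Liability-scale SNP heritability for one case/control phenotype.

    ``grm`` (and ``covariates``) cover the full cohort; individuals whose
    status is missing or excluded are dropped internally. ``blocks``, when
    given, is a partition of the *full* individual axis shared across
    phenotypes (indices absent from the analysis subset are ignored within
    each block), enabling difference jackknives with common blocks.
    """
    if assignment.degenerate:
        raise EstimationError(
            f"degenerate phenotype {assignment.definition.name!r}: "
            f"{assignment.n_cases} cases / {assignment.n_controls} controls"
        )
    status = assignment.status
    valid = (status == CASE) | (status == CONTROL)
    idx = np.flatnonzero(valid)
    y01 = (status[idx] == CASE).astype(np.float64)

    C = None
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        C = C[idx]
    resid = residualize(y01, C)
    sd = resid.std()
    if sd == 0:
        raise EstimationError("phenotype has zero variance after residualization")
    y = resid / sd

    G = grm.values[np.ix_(idx, idx)]
    ps = _PairStats(G, y)
    h2_obs = ps.slope(())

    P = float(y01.mean())
    K_val = float(K) if K is not None else float(assignment.K)
    cf = conversion_factor(K_val, P)

    # map full-axis blocks into subset coordinates
    if blocks is None:
        blocks = _blocks_from_seed(idx.size, n_blocks, seed)
        sub_blocks = blocks
    else:
        pos = np.full(status.size, -1, dtype=np.intp)
        pos[idx] = np.arange(idx.size)
        sub_blocks = [pos[b][pos[b] >= 0] for b in blocks]

    reps_obs = np.array([ps.slope(b) for b in sub_blocks])
    se_obs = _jackknife_se(reps_obs)

    return HeritabilityEstimate(
        h2_observed=h2_obs,
        h2_liability=h2_obs * cf,
        se_liability=se_obs * cf,
        K=K_val,
        P=P,
        n_cases=assignment.n_cases,
        n_controls=assignment.n_controls,
        se_observed=se_obs,
        block_replicates=reps_obs * cf,
    )
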