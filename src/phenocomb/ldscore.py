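"""Per-SNP association scans, LD scores and LD score regression.

The univariate model regresses GWAS chi-square statistics on LD scores,
E[chi2_j] = N h2 l_j / M + N a + 1, with a free intercept; the bivariate
model regresses z1_j*z2_j on l_j to estimate the genetic covariance, and
the genetic correlation is rg = gencov / sqrt(h2_1 h2_2). Regression
weights are a single-pass 1/max(l_j, 1); standard errors come from a
delete-one-block jackknife over 200 contiguous SNP blocks.

LD scores are computed on the panel itself: for SNP j,
l_j = sum over SNPs k within ``window_bp`` on the same chromosome of the
bias-adjusted squared correlation r2 - (1-r2)/(n-2), self term included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import GenotypePanel

__all__ = [
    "AssocSummary",
    "LDScoreTable",
    "H2Result",
    "RgEstimate",
    "linear_gwas",
    "run_gwas",
    "compute_ld_scores",
    "ldsc_h2",
    "ldsc_rg",
    "harmonize",
]

logger = logging.getLogger(__name__)


class LdscError(ValueError):
    """LD score regression undefined on the given inputs."""


@dataclass
class AssocSummary:
    """GWAS summary statistics aligned to a SNP map (LDSC-style columns)."""

    snp_ids: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    z: np.ndarray
    n_eff: np.ndarray

    @property
    def m(self) -> int:
        return self.snp_ids.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": self.snp_ids, "A1": self.a1, "A2": self.a2,
             "Z": self.z, "N": self.n_eff}
        )


@dataclass
class LDScoreTable:
    snp_ids: np.ndarray
    ell: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp_ids, "L2": self.ell})


@dataclass
class H2Result:
    h2: float
    intercept: float
    se: float
    n_snps: int
    block_replicates: Optional[np.ndarray] = None


@dataclass
class RgEstimate:
    rg: float
    se: float
    h2_1: float
    h2_2: float
    gencov: float
    intercepts: Tuple[float, float, float]
    n_snps: int
    block_replicates: Optional[np.ndarray] = None

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 1.0 if self.rg == 0 else 0.0
        return 2.0 * stats.norm.sf(abs(self.rg) / self.se)


def linear_gwas(dosages: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Simple-linear-regression z-scores of y on each dosage column.

    Monomorphic SNPs get z = NaN. Returns (z, n_eff).
    """
    X = np.asarray(dosages, dtype=np.float64)
    n, m = X.shape
    if n < 3:
        raise LdscError("need at least 3 individuals for a GWAS")
    yc = np.asarray(y, dtype=np.float64)
    yc = yc - yc.mean()
    xbar = X.mean(axis=0)
    Sxx = np.einsum("ij,ij->j", X, X) - n * xbar**2
    Sxy = X.T @ yc
    Syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Sxy / Sxx
        sigma2 = (Syy - beta * Sxy) / (n - 2)
        sigma2 = np.clip(sigma2, 0.0, None)
        se = np.sqrt(sigma2 / Sxx)
        z = beta / se
    mono = Sxx <= 0
    if mono.any():
        logger.warning("GWAS: %d monomorphic SNPs, z set to NaN", int(mono.sum()))
        z[mono] = np.nan
    return z, np.full(m, n, dtype=np.int64)


def run_gwas(panel: "GenotypePanel", y_resid: np.ndarray) -> AssocSummary:
    """GWAS of a residualized phenotype on every panel SNP."""
    y = np.asarray(y_resid, dtype=np.float64)
    if y.size != panel.n:
        raise LdscError("phenotype not aligned to the panel")
    if y.std() == 0:
        raise LdscError("phenotype has zero variance")
    z, n_eff = linear_gwas(panel.dosages, y)
    return AssocSummary(
        snp_ids=panel.snp_ids.copy(),
        a1=panel.a1.copy(),
        a2=panel.a2.copy(),
        z=z,
        n_eff=n_eff,
    )


def compute_ld_scores(panel: "GenotypePanel", window_bp: int = 1_000_000) -> LDScoreTable:
    """Panel LD scores with the small-sample bias adjustment.

    For each SNP the score sums r2 - (1-r2)/(n-2) over same-chromosome SNPs
    within ``window_bp`` (self term included, contributing exactly 1).
    """
    if window_bp < 0:
        raise LdscError("window_bp must be >= 0")
    n = panel.n
    if n <= 2:
        raise LdscError("need n > 2 individuals for bias-adjusted LD scores")
    ell = np.empty(panel.m, dtype=np.float64)
    for c in np.unique(panel.chrom):
        ix = np.flatnonzero(panel.chrom == c)
        X = np.asarray(panel.dosages[:, ix], dtype=np.float64)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise LdscError("monomorphic SNP in LD score computation")
        X /= sd
        R = (X.T @ X) / n
        r2 = R * R
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        bp = panel.bp[ix]
        in_window = np.abs(bp[:, None] - bp[None, :]) <= window_bp
        ell[ix] = np.where(in_window, r2_adj, 0.0).sum(axis=1)
    return LDScoreTable(snp_ids=panel.snp_ids.copy(), ell=ell)


def _wls_sums(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-observation stacked contributions (5 x n) to the WLS normal equations."""
    return np.vstack([w, w * x, w * y, w * x * x, w * x * y])


def _wls_solve(S: np.ndarray) -> Tuple[float, float]:
    Sw, Sx, Sy, Sxx, Sxy = S
    denom = Sw * Sxx - Sx * Sx
    if denom <= 0:
        raise LdscError("LD score variance is zero: slope unidentifiable")
    slope = (Sw * Sxy - Sx * Sy) / denom
    intercept = (Sy - slope * Sx) / Sw
    return float(slope), float(intercept)


def _default_blocks(n_snp: int, n_blocks: int) -> List[np.ndarray]:
    if n_blocks < 2 or n_blocks > n_snp:
        raise LdscError("n_blocks must be in [2, number of SNPs]")
    return [b for b in np.array_split(np.arange(n_snp), n_blocks)]


def _jackknife_se(replicates: np.ndarray) -> float:
    reps = replicates[np.isfinite(replicates)]
    B = reps.size
    if B < 2:
        return float("nan")
    return float(np.sqrt((B - 1) / B * ((reps - reps.mean()) ** 2).sum()))


def _align_ld(snp_ids: np.ndarray, ld: LDScoreTable) -> Tuple[np.ndarray, np.ndarray]:
    """Indices into ``snp_ids`` retained and the matching LD scores."""
    lut = pd.Series(ld.ell, index=ld.snp_ids)
    hit = pd.Index(snp_ids).isin(lut.index)
    keep = np.flatnonzero(hit)
    return keep, lut.loc[snp_ids[keep]].to_numpy()


def ldsc_h2(
    sumstats: AssocSummary,
    ld: LDScoreTable,
    m: int,
    *,
    n_blocks: int = 200,
    blocks: Optional[Sequence[np.ndarray]] = None,
) -> H2Result:
    """Univariate LD score regression.

    ``m`` is the number of SNPs the heritability is spread over (the
    denominator M of the regression model). ``blocks`` may supply a shared
    jackknife partition (index arrays into the aligned SNP order); by
    default 200 contiguous blocks in map order are used.
    """
    keep, ell = _align_ld(sumstats.snp_ids, ld)
    z = sumstats.z[keep]
    n_eff = sumstats.n_eff[keep]
    ok = np.isfinite(z)
    keep, ell, z, n_eff = keep[ok], ell[ok], z[ok], n_eff[ok]
    if keep.size < 50:
        raise LdscError(f"only {keep.size} SNPs shared between sumstats and LD scores")

    chi2 = z * z
    w = 1.0 / np.maximum(ell, 1.0)
    S = _wls_sums(ell, chi2, w)
    totals = S.sum(axis=1)
    slope, intercept = _wls_solve(totals)
    Nbar = float(n_eff.mean())
    h2 = slope * m / Nbar

    if blocks is None:
        blocks = _default_blocks(keep.size, n_blocks)
    reps = np.empty(len(blocks))
    for i, b in enumerate(blocks):
        s_b, _ = _wls_solve(totals - S[:, b].sum(axis=1))
        reps[i] = s_b * m / Nbar
    return H2Result(
        h2=h2, intercept=intercept, se=_jackknife_se(reps),
        n_snps=keep.size, block_replicates=reps,
    )


def harmonize(ss1: AssocSummary, ss2: AssocSummary) -> pd.DataFrame:
    """Inner-join two summary-statistic sets on SNP id with allele checks.

    Where the allele pair is swapped in ss2 its z sign is flipped; SNPs
    whose alleles cannot be reconciled are dropped (logged).
    """
    d1 = ss1.to_frame().rename(columns={"Z": "Z1", "N": "N1"})
    d2 = ss2.to_frame().rename(
        columns={"Z": "Z2", "N": "N2", "A1": "A1_2", "A2": "A2_2"}
    )
    df = d1.merge(d2, on="SNP", how="inner")
    same = (df["A1"] == df["A1_2"]) & (df["A2"] == df["A2_2"])
    flipped = (df["A1"] == df["A2_2"]) & (df["A2"] == df["A1_2"])
    bad = ~(same | flipped)
    if bad.any():
        logger.warning("harmonize: dropping %d SNPs with irreconcilable alleles",
                       int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
        same, flipped = same[~bad.values].values, flipped[~bad.values].values
    df.loc[np.asarray(flipped, dtype=bool), "Z2"] *= -1.0
    return df[["SNP", "A1", "A2", "Z1", "N1", "Z2", "N2"]]


def ldsc_rg(
    ss1: AssocSummary,
    ss2: AssocSummary,
    ld: LDScoreTable,
    m: int,
    *,
    n_blocks: int = 200,
    blocks: Optional[Sequence[np.ndarray]] = None,
) -> RgEstimate:
    """Bivariate LD score regression genetic correlation.

    The jackknife resamples the full ratio gencov/sqrt(h2_1 h2_2) over SNP
    blocks; replicates where either univariate slope is non-positive are
    dropped from the SE (logged through NaN replicates).
    """
    df = harmonize(ss1, ss2)
    keep, ell = _align_ld(df["SNP"].to_numpy(), ld)
    df = df.iloc[keep]
    z1 = df["Z1"].to_numpy()
    z2 = df["Z2"].to_numpy()
    ok = np.isfinite(z1) & np.isfinite(z2)
    df, ell, z1, z2 = df[ok], ell[ok], z1[ok], z2[ok]
    n_snp = z1.size
    if n_snp < 50:
        raise LdscError(f"only {n_snp} SNPs usable for rg")

    N1 = float(df["N1"].mean())
    N2 = float(df["N2"].mean())
    w = 1.0 / np.maximum(ell, 1.0)
    S1 = _wls_sums(ell, z1 * z1, w)
    S2 = _wls_sums(ell, z2 * z2, w)
    Sx = _wls_sums(ell, z1 * z2, w)
    t1, t2, tx = S1.sum(axis=1), S2.sum(axis=1), Sx.sum(axis=1)

    s1, i1 = _wls_solve(t1)
    s2, i2 = _wls_solve(t2)
    sx, ix_ = _wls_solve(tx)
    h2_1 = s1 * m / N1
    h2_2 = s2 * m / N2
    gencov = sx * m / np.sqrt(N1 * N2)
    if h2_1 <= 0 or h2_2 <= 0:
        raise LdscError(
            f"rg undefined: univariate h2 estimates {h2_1:.4f}, {h2_2:.4f} "
            "must both be positive"
        )
    rg = gencov / np.sqrt(h2_1 * h2_2)
    if abs(rg) > 1.25:
        logger.warning("rg estimate %.3f exceeds 1.25 in magnitude", rg)

    if blocks is None:
        blocks = _default_blocks(n_snp, n_blocks)
    reps = np.empty(len(blocks))
    for i, b in enumerate(blocks):
        bsum1 = t1 - S1[:, b].sum(axis=1)
        bsum2 = t2 - S2[:, b].sum(axis=1)
        bsumx = tx - Sx[:, b].sum(axis=1)
        b1, _ = _wls_solve(bsum1)
        b2, _ = _wls_solve(bsum2)
        bx, _ = _wls_solve(bsumx)
        hb1 = b1 * m / N1
        hb2 = b2 * m / N2
        if hb1 <= 0 or hb2 <= 0:
            reps[i] = np.nan
        else:
            reps[i] = (bx * m / np.sqrt(N1 * N2)) / np.sqrt(hb1 * hb2)
    return RgEstimate(
        rg=float(rg), se=_jackknife_se(reps), h2_1=float(h2_1), h2_2=float(h2_2),
        gencov=float(gencov), intercepts=(i1, i2, ix_), n_snps=n_snp,
        block_replicates=reps,
    )
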