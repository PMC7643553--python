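"""SNP filtering, lncRNA-region SNP annotation and Q+K mixed-model GWAS.

The association model is the classic Q+K mixed linear model

    y = X beta + g + e,      g ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with fixed effects X = [intercept, Q (population admixture covariates),
SNP dosage] and the kinship matrix K defining the polygenic covariance.
Variance components are estimated once by REML under the null model
(without any SNP) via the spectral decomposition of K, then reused for a
generalised-least-squares Wald test per SNP -- the single-estimation
approximation that keeps a genome scan tractable.

The model is exposed statsmodels-style: build a :class:`QKMixedModel` from
data, call :meth:`~QKMixedModel.fit` for a :class:`QKMixedModelResults`
object carrying the variance components, then
:meth:`~QKMixedModelResults.scan` for the per-SNP association table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeTable, LncRnaLocus, TranscriptModel

logger = logging.getLogger(__name__)

MAF_MIN = 0.05         # strict: MAF must exceed this
CALL_RATE_MIN = 0.80   # strict: call rate must exceed this
P_CUTOFF = 1e-3


def filter_snps(
    table: GenotypeTable,
    maf_min: float = MAF_MIN,
    call_rate_min: float = CALL_RATE_MIN,
) -> GenotypeTable:
    """Retain SNPs with MAF > maf_min and call rate > call_rate_min (both strict)."""
    if table.n_snps == 0:
        return table
    maf = table.maf()
    call_rate = table.call_rate()
    keep = (maf > maf_min) & (call_rate > call_rate_min)
    return table.subset(keep)


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Fraction of non-missing individuals heterozygous at one SNP."""
    calls = np.asarray(calls)
    observed = calls != GenotypeTable.MISSING
    if not observed.any():
        raise ValueError("all calls missing")
    return float((calls == 1).sum() / observed.sum())


def snps_in_lncrna(
    table: GenotypeTable,
    loci: list[LncRnaLocus],
    transcripts: dict[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Assign SNPs to every lncRNA locus whose span contains them.

    Context is ``exon`` when the position falls inside any member
    transcript's exon, else ``intron``; a SNP spanning two overlapping loci
    yields one record per locus.
    """
    maf = table.maf()
    call_rate = table.call_rate()
    het = table.heterozygosity()
    records = []
    for i, row in table.snps.iterrows():
        pos = int(row["pos"])
        for locus in loci:
            if locus.chrom != row["chrom"] or not (locus.start <= pos < locus.end):
                continue
            # exon/intron context needs member exon structure; without it a
            # SNP inside the span defaults to intron
            context = "intron"
            if transcripts is not None:
                for tid in locus.members:
                    tx = transcripts.get(tid)
                    if tx and any(s <= pos < e for s, e in tx.exons):
                        context = "exon"
                        break
            records.append(
                {
                    "snp_id": row["snp_id"],
                    "locus_id": locus.locus_id,
                    "chrom": row["chrom"],
                    "pos": pos,
                    "context": context,
                    "maf": maf[i],
                    "call_rate": call_rate[i],
                    "het": het[i],
                }
            )
    return pd.DataFrame(
        records,
        columns=["snp_id", "locus_id", "chrom", "pos", "context", "maf", "call_rate", "het"],
    )


def kinship_matrix(table: GenotypeTable) -> np.ndarray:
    """VanRaden kinship: centred-dosage cross-product / (2 sum p(1-p)).

    Missing calls are mean-imputed per SNP.  Monomorphic SNPs contribute
    nothing; a table with no polymorphic SNP is an error.
    """
    d = table.imputed_dosage()
    p = d.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for kinship estimation")
    z = d[poly] - 2.0 * p[poly, None]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    k = z.T @ z / denom
    return (k + k.T) / 2.0


def _drop_last_column(q: np.ndarray) -> np.ndarray:
    """Drop the last admixture column (rows sum to 1, collinear with intercept)."""
    if q.ndim != 2 or q.shape[1] == 0:
        return np.empty((q.shape[0], 0))
    return q[:, :-1]


def build_fixed_effects(n: int, q: np.ndarray | None) -> np.ndarray:
    x = [np.ones((n, 1))]
    if q is not None:
        q = np.asarray(q, dtype=float)
        if np.allclose(q.sum(axis=1), 1.0):
            q = _drop_last_column(q)
        if q.shape[1]:
            x.append(q)
    return np.hstack(x)


class QKMixedModel:
    """Q+K mixed linear model for one quantitative trait.

    Parameters
    ----------
    y : (n,) phenotype vector.
    K : (n, n) symmetric kinship matrix.
    Q : optional (n, k) admixture proportions; when rows sum to 1 the last
        column is dropped to avoid collinearity with the intercept.
    """

    def __init__(
        self,
        y: np.ndarray | pd.Series,
        K: np.ndarray,
        Q: np.ndarray | pd.DataFrame | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError("K must be n x n")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        self.K = K
        self.X = build_fixed_effects(n, None if Q is None else np.asarray(Q, dtype=float))
        if n < self.X.shape[1] + 2:
            raise ValueError("too few individuals for the fixed effects")
        # spectral decomposition of K, shared by REML and the scan
        self._eigvals, self._eigvecs = np.linalg.eigh(self.K)
        self._eigvals = np.clip(self._eigvals, 0.0, None)
        self._y_rot = self._eigvecs.T @ self.y
        self._x_rot = self._eigvecs.T @ self.X

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        trait: str,
        K: np.ndarray,
        q_columns: list[str] | None = None,
    ) -> "QKMixedModel":
        q = data[q_columns].to_numpy() if q_columns else None
        return cls(data[trait].to_numpy(), K, q)

    # -- REML ---------------------------------------------------------------

    def _neg_restricted_loglik(self, log_lambda: float) -> float:
        lam = np.exp(log_lambda)
        return -self._restricted_loglik(lam)

    def _restricted_loglik(self, lam: float) -> float:
        w = 1.0 / (lam * self._eigvals + 1.0)
        xtwx = self._x_rot.T @ (w[:, None] * self._x_rot)
        xtwy = self._x_rot.T @ (w * self._y_rot)
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular fixed-effect system at lambda={lam:g}") from exc
        resid = self._y_rot - self._x_rot @ beta
        n, p = self._x_rot.shape
        rss = float(resid @ (w * resid))
        if not np.isfinite(rss) or rss <= 0:
            raise ValueError(f"non-finite restricted likelihood at lambda={lam:g}")
        sigma_e2 = rss / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        _, logdet_xtx = np.linalg.slogdet(self.X.T @ self.X)
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
            - np.log(w).sum()
            + logdet_xtwx
            - logdet_xtx
        )
        return ll

    def fit(self, grid: np.ndarray | None = None) -> "QKMixedModelResults":
        """REML estimation of (sigma_g^2, sigma_e^2).

        The variance ratio lambda = sigma_g^2 / sigma_e^2 is profiled over a
        log-spaced grid and refined by bounded scalar optimisation around
        the best bracket; deterministic for fixed inputs.
        """
        if grid is None:
            grid = np.logspace(-5, 5, 41)
        log_grid = np.log(grid)
        ll = np.array([self._restricted_loglik(lam) for lam in grid])
        best = int(np.argmax(ll))
        lo = log_grid[max(best - 1, 0)]
        hi = log_grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                self._neg_restricted_loglik, bounds=(lo, hi), method="bounded"
            )
            log_lam = float(res.x)
        else:
            log_lam = float(log_grid[best])
        # allow the boundary (sigma_g^2 ~ 0) to win outright
        if ll[0] >= self._restricted_loglik(np.exp(log_lam)):
            log_lam = log_grid[0]
        lam = float(np.exp(log_lam))
        w = 1.0 / (lam * self._eigvals + 1.0)
        xtwx = self._x_rot.T @ (w[:, None] * self._x_rot)
        beta = np.linalg.solve(xtwx, self._x_rot.T @ (w * self._y_rot))
        resid = self._y_rot - self._x_rot @ beta
        n, p = self._x_rot.shape
        sigma_e2 = float(resid @ (w * resid)) / (n - p)
        sigma_g2 = lam * sigma_e2
        if lam <= grid[0] * 1.0001:
            sigma_g2 = 0.0  # boundary estimate: no detectable polygenic variance
        return QKMixedModelResults(
            model=self,
            lambda_=lam,
            sigma_g2=sigma_g2,
            sigma_e2=sigma_e2,
            beta=beta,
            restricted_loglik=self._restricted_loglik(lam),
        )


@dataclass
class QKMixedModelResults:
    """REML fit of the null Q+K model; entry point for the SNP scan."""

    model: QKMixedModel
    lambda_: float
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    restricted_loglik: float

    @property
    def heritability(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Q+K mixed linear model (REML)",
            f"  individuals:        {len(self.model.y)}",
            f"  fixed effects:      {self.model.X.shape[1]} (intercept + Q)",
            f"  sigma_g^2:          {self.sigma_g2:.4f}",
            f"  sigma_e^2:          {self.sigma_e2:.4f}",
            f"  h^2 (sg2/(sg2+se2)): {self.heritability:.4f}",
            f"  restricted loglik:  {self.restricted_loglik:.3f}",
        ]
        return "\n".join(lines)

    def scan(
        self,
        genotypes: GenotypeTable | np.ndarray,
        cutoff: float = P_CUTOFF,
        snp_ids: list[str] | None = None,
        trait: str = "trait",
    ) -> pd.DataFrame:
        """Per-SNP generalised least squares Wald test.

        Genotype dosages (0/1/2, missing mean-imputed) enter as the last
        fixed effect; the test statistic is t = beta_snp / se with
        n - p degrees of freedom.  Monomorphic SNPs are skipped with a
        warning.  Returns a frame sorted by p within the trait.
        """
        if isinstance(genotypes, GenotypeTable):
            dosage = genotypes.imputed_dosage()
            if snp_ids is None:
                snp_ids = list(genotypes.snps["snp_id"])
        else:
            dosage = np.asarray(genotypes, dtype=float)
            if dosage.ndim == 1:
                dosage = dosage[None, :]
            if snp_ids is None:
                snp_ids = [f"snp{i}" for i in range(dosage.shape[0])]
        m = self.model
        w = 1.0 / (self.lambda_ * m._eigvals + 1.0)
        n, p0 = m._x_rot.shape
        dfree = n - (p0 + 1)
        records = []
        for j in range(dosage.shape[0]):
            x = dosage[j]
            if np.ptp(x) == 0:
                logger.warning("skipping monomorphic SNP %s", snp_ids[j])
                continue
            x_rot = m._eigvecs.T @ x
            X = np.column_stack([m._x_rot, x_rot])
            xtwx = X.T @ (w[:, None] * X)
            xtwy = X.T @ (w * m._y_rot)
            try:
                xtwx_inv = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                logger.warning("skipping collinear SNP %s", snp_ids[j])
                continue
            beta = xtwx_inv @ xtwy
            resid = m._y_rot - X @ beta
            sigma2 = float(resid @ (w * resid)) / dfree
            se = np.sqrt(sigma2 * xtwx_inv[-1, -1])
            tstat = beta[-1] / se
            p = float(2.0 * stats.t.sf(abs(tstat), dfree))
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            records.append(
                {
                    "snp_id": snp_ids[j],
                    "trait": trait,
                    "effect": float(beta[-1]),
                    "t_stat": float(tstat),
                    "p_value": p,
                    "neg_log10_p": float(-np.log10(p)),
                    "significant": p < cutoff,
                }
            )
        frame = pd.DataFrame(
            records,
            columns=["snp_id", "trait", "effect", "t_stat", "p_value", "neg_log10_p", "significant"],
        )
        return frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)


# -- functional wrappers over the model objects -----------------------------

def reml_variance_components(
    y: np.ndarray,
    K: np.ndarray,
    Q: np.ndarray | None = None,
) -> tuple[float, float]:
    """REML (sigma_g^2, sigma_e^2) under the null model [intercept + Q]."""
    results = QKMixedModel(y, K, Q).fit()
    return results.sigma_g2, results.sigma_e2


def mlm_scan(
    y: np.ndarray | pd.Series,
    genotypes: GenotypeTable,
    Q: np.ndarray | None,
    K: np.ndarray,
    cutoff: float = P_CUTOFF,
    trait: str = "trait",
) -> pd.DataFrame:
    """Fit the null Q+K model once, then scan every SNP (EMMAX-style)."""
    results = QKMixedModel(y, K, Q).fit()
    return results.scan(genotypes, cutoff=cutoff, trait=trait)


def mlm_scan_traits(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    Q: np.ndarray | None,
    K: np.ndarray,
    cutoff: float = P_CUTOFF,
) -> pd.DataFrame:
    """Scan every trait column of a phenotype table; concatenated results."""
    frames = []
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        frames.append(mlm_scan(y, genotypes, Q, K, cutoff=cutoff, trait=trait))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
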