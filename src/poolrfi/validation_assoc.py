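"""Independent-population validation: pedigree BLUP, Wald tests, genotype effects.

The animal model is y = Xb + Za + e with a ~ N(0, A * sigma2_a) where A is
the numerator relationship matrix from the pedigree (tabular method).
Breeding values are predicted from Henderson's mixed-model equations;
variance components can be estimated by EM-REML. Per SNP, breeding values
are regressed on allele dosage (Wald chi-square test) and raw phenotypes are
modelled as sex + genotype fixed effects to obtain least-squares means, from
which additive and dominance effects derive as half the homozygote contrast
and the heterozygote deviation from the homozygote midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PedigreeTable

__all__ = [
    "MixedModelSpec",
    "MixedModelSolution",
    "build_a_matrix",
    "solve_blup",
    "estimate_variance_components",
    "wald_snp_test",
    "genotype_lsm",
    "additive_dominance",
    "effects_from_lsm",
]


# ---------------------------------------------------------------------------
# Relationship matrix
# ---------------------------------------------------------------------------


def build_a_matrix(pedigree: PedigreeTable) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular method.

    Returns (A, ids) with ids in topological (parents-first) order:
    A_ii = 1 + 0.5 * A_{sire,dam}; A_ij = 0.5 * (A_{j,sire} + A_{j,dam})
    with unknown parents contributing zero.
    """
    order = pedigree.topological_order()
    index = {animal: i for i, animal in enumerate(order)}
    by_id = {r.animal_id: r for r in pedigree.records}
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        rec = by_id[animal]
        s = index.get(rec.sire_id) if rec.sire_id else None
        d = index.get(rec.dam_id) if rec.dam_id else None
        if i > 0:
            row = np.zeros(i)
            if s is not None:
                row += 0.5 * A[s, :i]
            if d is not None:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
    return A, order


# ---------------------------------------------------------------------------
# BLUP / mixed-model equations
# ---------------------------------------------------------------------------


@dataclass
class MixedModelSpec:
    """Inputs to the animal model y = Xb + Za + e."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    A: np.ndarray
    sigma2_a: float
    sigma2_e: float
    animal_ids: Sequence[str] | None = None

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_a

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X and Z must have one row per observation")
        if self.A.shape[0] != self.A.shape[1] or self.A.shape[0] != self.Z.shape[1]:
            raise ValueError("A must be square and conformable with Z")
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")


@dataclass
class MixedModelSolution:
    b_hat: np.ndarray
    ebv: np.ndarray
    relative_residual: float
    animal_ids: Sequence[str] | None = None

    def ebv_series(self) -> pd.Series:
        index = self.animal_ids if self.animal_ids is not None else range(len(self.ebv))
        return pd.Series(self.ebv, index=list(index), name="ebv")


def _assemble_mme(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, A: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Ainv = np.linalg.inv(A)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * Ainv])
    M = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return M, rhs, Ainv


def solve_blup(spec: MixedModelSpec, tol: float = 1e-8) -> MixedModelSolution:
    """Solve Henderson's mixed-model equations for fixed effects and EBVs."""
    M, rhs, _ = _assemble_mme(spec.y, spec.X, spec.Z, spec.A, spec.lambda_)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"mixed-model coefficient matrix ill-conditioned (cond={cond:.3g})"
        )
    sol = np.linalg.solve(M, rhs)
    rel = float(np.linalg.norm(M @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    if rel > tol:
        raise np.linalg.LinAlgError(f"MME residual {rel:.3g} exceeds tolerance {tol:g}")
    p = spec.X.shape[1]
    return MixedModelSolution(
        b_hat=sol[:p],
        ebv=sol[p:],
        relative_residual=rel,
        animal_ids=spec.animal_ids,
    )


@dataclass
class RemlResult:
    sigma2_a: float
    sigma2_e: float
    n_iterations: int
    converged: bool
    at_boundary: bool = False
    history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    tol: float = 1e-6,
    max_iterations: int = 500,
) -> RemlResult:
    """EM-REML estimates of (sigma2_a, sigma2_e) for the animal model.

    Iterates the expectation-maximization updates on the mixed-model
    equations until both components change by less than ``tol`` (relative)
    or ``max_iterations`` is reached. A vanishing additive component is
    returned as a flagged boundary estimate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A, dtype=float)
    n = len(y)
    p = int(np.linalg.matrix_rank(X))
    if n <= p + 1:
        raise ValueError("not enough observations to estimate variance components")
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise ValueError("phenotype has zero variance")
    q = A.shape[0]
    sigma2_a = 0.5 * var_y
    sigma2_e = 0.5 * var_y
    yty = float(y @ y)

    # Canonical transformation: with a = L u (A = L L'), the MME a-block
    # becomes W'W + lambda I with W = Z L, and tr(A^-1 C_aa) = tr(C_uu).
    # After eigendecomposing W'W = Q diag(D) Q' once, each EM iteration is
    # O(q p^2) (Woodbury correction for the p fixed-effect columns).
    L = np.linalg.cholesky(A)
    W = Z @ L
    D, Q = np.linalg.eigh(W.T @ W)
    D = np.maximum(D, 0.0)
    B = Q.T @ (W.T @ X)  # q x p
    c = Q.T @ (W.T @ y)  # q
    E = X.T @ X  # p x p
    Xty = X.T @ y

    history: list[tuple[float, float]] = []
    converged = False
    n_iter = 0
    boundary_floor = 1e-8 * var_y
    for n_iter in range(1, max_iterations + 1):
        lam = sigma2_e / sigma2_a
        s = D + lam  # diagonal of the rotated a-block
        sinv = 1.0 / s
        # fixed effects after absorbing the random effects
        Es = E - B.T @ (B * sinv[:, None])
        Es_inv = np.linalg.inv(Es)
        b_hat = Es_inv @ (Xty - B.T @ (sinv * c))
        v = sinv * (c - B @ b_hat)  # rotated, whitened breeding values
        # tr(C_uu) via Woodbury on (S - B E^-1 B')^-1
        Bs = B * sinv[:, None]
        tr_Cuu = float(sinv.sum() + np.einsum("ij,jk,ik->", Bs, Es_inv, Bs))
        new_a = (float(v @ v) + sigma2_e * tr_Cuu) / q
        new_e = (yty - float(b_hat @ Xty) - float(v @ c)) / (n - p)
        history.append((new_a, new_e))
        if new_a < boundary_floor:
            return RemlResult(
                sigma2_a=float(max(new_a, 0.0)),
                sigma2_e=float(new_e),
                n_iterations=n_iter,
                converged=True,
                at_boundary=True,
                history=history,
            )
        rel_a = abs(new_a - sigma2_a) / max(sigma2_a, 1e-30)
        rel_e = abs(new_e - sigma2_e) / max(sigma2_e, 1e-30)
        sigma2_a, sigma2_e = float(new_a), float(new_e)
        if rel_a < tol and rel_e < tol:
            converged = True
            break
    return RemlResult(
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        n_iterations=n_iter,
        converged=converged,
        history=history,
    )


# ---------------------------------------------------------------------------
# Per-SNP association
# ---------------------------------------------------------------------------


def wald_snp_test(
    ebv: np.ndarray, dosage: np.ndarray
) -> tuple[float, float, float]:
    """Wald test of EBV on allele dosage: (beta, se, p).

    Missing dosages (NaN) are dropped pairwise. Monomorphic SNPs return
    p = 1 with NaN estimates. p is clamped below at 1e-300.
    """
    ebv = np.asarray(ebv, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(dosage) & ~np.isnan(ebv)
    x, yv = dosage[ok], ebv[ok]
    if len(np.unique(x)) < 2:
        return float("nan"), float("nan"), 1.0
    n = len(x)
    sxx = float(((x - x.mean()) ** 2).sum())
    beta = float(((x - x.mean()) * (yv - yv.mean())).sum() / sxx)
    alpha = yv.mean() - beta * x.mean()
    resid = yv - alpha - beta * x
    dof = n - 2
    if dof <= 0:
        return beta, float("nan"), 1.0
    s2 = float(resid @ resid) / dof
    se = float(np.sqrt(s2 / sxx))
    if se == 0.0:
        return beta, 0.0, 1e-300
    wald = (beta / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return beta, se, max(p, 1e-300)


def _letter_groups(means: np.ndarray, significant: np.ndarray, letters: str) -> list[str]:
    """Compact letter display: classes sharing a letter do not differ.

    Maximal runs of the mean-sorted classes containing no significant pair
    each receive one letter.
    """
    k = len(means)
    order = np.argsort(means, kind="mergesort")

    def compatible(i: int, j: int) -> bool:
        return not any(
            significant[order[u], order[v]]
            for u in range(i, j + 1)
            for v in range(u + 1, j + 1)
        )

    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and compatible(i, j + 1):
            j += 1
        runs.append((i, j))
    maximal = sorted(
        {
            r
            for r in runs
            if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)
        }
    )
    out = [""] * k
    for letter_idx, (lo, hi) in enumerate(maximal):
        for t in range(lo, hi + 1):
            out[order[t]] += letters[letter_idx % len(letters)]
    return out


def genotype_lsm(
    y: np.ndarray,
    genotype: Sequence[str],
    sex: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Least-squares genotype means from the model y ~ sex + genotype.

    Returns a per-class table (genotype, n, lsm, se, letters at 0.05/0.01)
    sorted by genotype label, and the overall genotype F-test p-value. LSMs
    are model predictions averaged with equal weight over sex levels.
    """
    y = np.asarray(y, dtype=float)
    genotype = np.asarray(genotype, dtype=object)
    sex = np.asarray(sex, dtype=object)
    ok = ~np.isnan(y) & (genotype != None)  # noqa: E711
    y, genotype, sex = y[ok], genotype[ok], sex[ok]
    g_levels = sorted(set(genotype))
    s_levels = sorted(set(sex))
    if len(g_levels) < 2:
        raise ValueError("need >= 2 genotype classes")
    n = len(y)
    # treatment coding, first level as reference
    X_parts = [np.ones((n, 1))]
    for lvl in s_levels[1:]:
        X_parts.append((sex == lvl).astype(float)[:, None])
    for lvl in g_levels[1:]:
        X_parts.append((genotype == lvl).astype(float)[:, None])
    X = np.hstack(X_parts)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)

    n_s = len(s_levels)

    def lsm_contrast(g_idx: int) -> np.ndarray:
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        for j in range(1, n_s):
            c[j] = 1.0 / n_s  # average over sex levels
        if g_idx > 0:
            c[n_s - 1 + g_idx] = 1.0
        return c

    contrasts = [lsm_contrast(i) for i in range(len(g_levels))]
    lsms = np.array([c @ beta for c in contrasts])
    ses = np.array([np.sqrt(s2 * c @ XtX_inv @ c) for c in contrasts])

    # overall genotype F-test: full model vs sex-only
    X_red = np.hstack(X_parts[:n_s])
    beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_r = float(((y - X_red @ beta_r) ** 2).sum())
    df_num = len(g_levels) - 1
    if rss <= 0:
        overall_p = 0.0 if rss_r > rss else 1.0
    else:
        F = ((rss_r - rss) / df_num) / s2
        overall_p = float(stats.f.sf(F, df_num, dof))

    # pairwise contrasts for letter groupings
    k = len(g_levels)
    sig05 = np.zeros((k, k), dtype=bool)
    sig01 = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            c = contrasts[i] - contrasts[j]
            se_d = np.sqrt(s2 * c @ XtX_inv @ c)
            if se_d == 0:
                p_pair = 1.0
            else:
                t = (c @ beta) / se_d
                p_pair = 2 * stats.t.sf(abs(t), dof)
            sig05[i, j] = sig05[j, i] = p_pair < 0.05
            sig01[i, j] = sig01[j, i] = p_pair < 0.01
    letters05 = _letter_groups(lsms, sig05, "abcdefgh")
    letters01 = _letter_groups(lsms, sig01, "ABCDEFGH")

    counts = [int((genotype == lvl).sum()) for lvl in g_levels]
    table = pd.DataFrame(
        {
            "genotype": g_levels,
            "n": counts,
            "lsm": lsms,
            "se": ses,
            "letters_05": letters05,
            "letters_01": letters01,
        }
    )
    return table, overall_p


def additive_dominance(
    lsm_hom1: float, lsm_het: float, lsm_hom2: float
) -> tuple[float, float]:
    """Additive and dominance effects from three genotype-class means.

    a = (hom1 - hom2) / 2 with hom1 the alphabetically first homozygote;
    d = het - (hom1 + hom2) / 2.
    """
    a_eff = (lsm_hom1 - lsm_hom2) / 2.0
    d_eff = lsm_het - (lsm_hom1 + lsm_hom2) / 2.0
    return a_eff, d_eff


def effects_from_lsm(lsm_by_genotype: Mapping[str, float]) -> tuple[float, float]:
    """Additive/dominance effects from a {genotype label: LSM} mapping.

    Homozygote labels have two identical alleles; the alphabetically first
    homozygote fixes the sign of the additive effect.
    """
    homs = sorted(g for g in lsm_by_genotype if len(set(g)) == 1)
    hets = [g for g in lsm_by_genotype if len(set(g)) > 1]
    if len(homs) != 2 or len(hets) != 1:
        raise ValueError(
            f"need two homozygote and one heterozygote class, got {sorted(lsm_by_genotype)}"
        )
    return additive_dominance(
        lsm_by_genotype[homs[0]], lsm_by_genotype[hets[0]], lsm_by_genotype[homs[1]]
    )
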