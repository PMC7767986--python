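"""Weighted GBLUP on deregressed proofs (DRP).

The model is y = Xb + Zu + e with Var(u) = G sigma2_g and Var(e) = E sigma2_e,
where E is diagonal with entries 1/w_i and w_i is the DRP weight of animal i.
Weights differ between cows (record count n, repeatability t) and bulls
(daughter count p), following the standard deregressed-proof weighting with a
fraction c of genetic variance not captured by markers:

    w_cow  = (1 - h2) / ( c*h2 + [1 + (n-1)*t]/n - h2 )
    w_bull = (1 - h2) / ( c*h2 + (4 - h2)/p )

Validation animals enter the mixed-model equations with zero incidence rows
and receive GEBV through the G-inverse coupling, which is algebraically the
conditional mean given the reference solutions.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .markers import GRM

log = logging.getLogger(__name__)

__all__ = [
    "WeightParams",
    "DRPTable",
    "GBLUPFit",
    "cow_weight",
    "bull_weight",
    "cow_reliability",
    "bull_reliability",
    "build_design_matrix",
    "fit_wgblup",
]


@dataclass(frozen=True)
class WeightParams:
    """Heritability h2, repeatability t and unexplained-variance fraction c."""

    h2: float = 0.33
    t: float = 0.56
    c: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must be in (0,1), got {self.h2}")
        if not self.h2 <= self.t < 1.0:
            raise ValueError(f"t must be in [h2, 1), got {self.t}")
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"c must be in (0,1), got {self.c}")


def cow_weight(params: WeightParams, n) -> np.ndarray | float:
    """DRP weight for a cow with ``n`` own records."""
    n = np.asarray(n, dtype=np.float64)
    if np.any(n < 1):
        raise ValueError("cow record count n must be >= 1")
    denom = params.c * params.h2 + (1.0 + (n - 1.0) * params.t) / n - params.h2
    if np.any(denom <= 0):
        raise ValueError("non-positive weight denominator: inconsistent (h2, t, c)")
    w = (1.0 - params.h2) / denom
    return float(w) if w.ndim == 0 else w


def bull_weight(params: WeightParams, p) -> np.ndarray | float:
    """DRP weight for a bull with ``p`` daughters."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 1):
        raise ValueError("bull daughter count p must be >= 1")
    denom = params.c * params.h2 + (4.0 - params.h2) / p
    w = (1.0 - params.h2) / denom
    return float(w) if w.ndim == 0 else w


def cow_reliability(params: WeightParams, n) -> np.ndarray | float:
    """DRP reliability for a cow with ``n`` records: n h2 / (1 + (n-1) t)."""
    n = np.asarray(n, dtype=np.float64)
    r2 = n * params.h2 / (1.0 + (n - 1.0) * params.t)
    return float(r2) if r2.ndim == 0 else r2


def bull_reliability(params: WeightParams, p) -> np.ndarray | float:
    """DRP reliability for a bull with ``p`` daughters: p / (p + (4-h2)/h2)."""
    p = np.asarray(p, dtype=np.float64)
    r2 = p / (p + (4.0 - params.h2) / params.h2)
    return float(r2) if r2.ndim == 0 else r2


@dataclass
class DRPTable:
    """Per-animal deregressed-proof records for one trait.

    One record per animal per trait; ``weight`` carries the DRP weight w_i
    (the residual matrix E has diagonal 1/w_i), and ``n_eff`` the record count
    (cows) or daughter count (bulls) it was derived from.
    """

    animal_ids: np.ndarray
    y: np.ndarray
    sex: np.ndarray          # "cow" / "bull"
    breed_group: np.ndarray  # e.g. H, 75H25J, 50H50J, 25H75J, J
    n_eff: np.ndarray
    weight: np.ndarray
    trait: str = "trait"

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.sex = np.asarray(self.sex, dtype=object)
        self.breed_group = np.asarray(self.breed_group, dtype=object)
        self.n_eff = np.asarray(self.n_eff, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        n = len(self.animal_ids)
        for name in ("y", "sex", "breed_group", "n_eff", "weight"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match animal_ids")
        if len(set(self.animal_ids)) != n:
            raise ValueError("one record per animal per trait: duplicate animal id")
        if np.any(self.weight <= 0):
            raise ValueError("DRP weights must be positive")

    def __len__(self) -> int:
        return len(self.animal_ids)

    def subset(self, ids) -> "DRPTable":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([lookup[a] for a in ids], dtype=np.int64)
        return DRPTable(self.animal_ids[idx], self.y[idx], self.sex[idx],
                        self.breed_group[idx], self.n_eff[idx], self.weight[idx],
                        self.trait)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_ids, "trait": self.trait, "drp": self.y,
            "sex": self.sex, "breed_group": self.breed_group,
            "n_eff": self.n_eff, "weight": self.weight,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DRPTable":
        traits = df["trait"].unique()
        if len(traits) != 1:
            raise ValueError("DRPTable holds one trait; filter the frame first")
        return cls(df["animal_id"].to_numpy(), df["drp"].to_numpy(),
                   df["sex"].to_numpy(), df["breed_group"].to_numpy(),
                   df["n_eff"].to_numpy(), df["weight"].to_numpy(),
                   trait=str(traits[0]))


@dataclass
class GBLUPFit:
    """Solution of the weighted GBLUP mixed-model equations."""

    fixed_effects: pd.Series
    gebv: pd.Series           # indexed by every animal in the GRM
    sigma2_g: float
    sigma2_e: float
    lam: float
    solver_residual: float
    reml_converged: bool = True


def build_design_matrix(sex, breed_group):
    """Fixed-effect design: intercept + sex + breed-group dummies.

    The first level of each factor is the reference level. Columns that are
    aliased with earlier columns are dropped (left-to-right greedy rank check),
    i.e. the later aliased level is the one removed.
    """
    sex = np.asarray(sex, dtype=object)
    breed_group = np.asarray(breed_group, dtype=object)
    n = len(sex)
    cols = [np.ones(n)]
    names = ["intercept"]
    for label, values in (("sex", sex), ("breed_group", breed_group)):
        levels = sorted(set(values))
        for lev in levels[1:]:
            cols.append((values == lev).astype(np.float64))
            names.append(f"{label}[{lev}]")
    X = np.column_stack(cols)
    # greedy left-to-right: keep a column only if it increases rank
    keep = []
    rank = 0
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(f"dropping aliased fixed-effect column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


def _mme_solve(X, y, w, Ginv_lam, phen_idx, q):
    """Assemble and solve the weighted mixed-model equations.

    One record per animal, so Z is a selection matrix: Z'DZ contributes
    diag(w) on the phenotyped animals only.
    """
    p = X.shape[1]
    D = w  # diagonal of E^{-1}
    XtDX = X.T @ (X * D[:, None])
    XtDy = X.T @ (D * y)
    C = np.zeros((p + q, p + q))
    rhs = np.zeros(p + q)
    C[:p, :p] = XtDX
    ZtDX = np.zeros((q, p))
    ZtDX[phen_idx] = X * D[:, None]
    C[:p, p:] = ZtDX.T
    C[p:, :p] = ZtDX
    C[p:, p:] = Ginv_lam
    C[p + phen_idx, p + phen_idx] += D
    rhs[:p] = XtDy
    zt = np.zeros(q)
    zt[phen_idx] = D * y
    rhs[p:] = zt
    try:
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "mixed-model equations singular after ridge; check design and GRM"
        ) from e
    resid = np.max(np.abs(C @ sol - rhs))
    return sol, resid, C


def fit_wgblup(
    drp: DRPTable,
    grm: GRM,
    params: WeightParams | None = None,
    variance_mode: str = "fixed",
    sigma2_g: float = 1.0,
    sigma2_e: float | None = None,
    ridge: float = 1e-6,
    reml_tol: float = 1e-6,
    reml_max_iter: int = 200,
) -> GBLUPFit:
    """Solve weighted GBLUP for all animals in the GRM.

    Phenotyped animals are the rows of ``drp``; every other GRM animal is
    treated as unphenotyped (zero incidence) and predicted through G. With
    ``variance_mode="fixed"`` the variance components are taken as given
    (``sigma2_e`` defaults to sigma2_g*(1-h2)/h2, the scale on which the DRP
    weights are calibrated); ``"em_reml"`` iterates EM-REML updates of
    (sigma2_g, sigma2_e) until relative change < ``reml_tol``.
    """
    if variance_mode not in ("fixed", "em_reml"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if params is None:
        params = WeightParams()
    if sigma2_e is None:
        sigma2_e = sigma2_g * (1.0 - params.h2) / params.h2

    q = len(grm.animal_ids)
    phen_idx = grm.animal_index(drp.animal_ids)  # raises on missing animals
    X, names = build_design_matrix(drp.sex, drp.breed_group)
    y = drp.y
    w = drp.weight
    n = len(y)

    G = grm.matrix.copy()
    if ridge:
        G[np.diag_indices_from(G)] += ridge
    cf_G = linalg.cho_factor(G, lower=True, check_finite=False)
    Ginv = linalg.cho_solve(cf_G, np.eye(q), check_finite=False)
    Ginv = 0.5 * (Ginv + Ginv.T)

    p = X.shape[1]
    converged = True
    if variance_mode == "em_reml":
        for _ in range(reml_max_iter):
            lam = sigma2_e / sigma2_g
            sol, _, C = _mme_solve(X, y, w, Ginv * lam, phen_idx, q)
            b, u = sol[:p], sol[p:]
            Cinv = linalg.inv(C)
            Cuu = Cinv[p:, p:]
            new_g = (u @ Ginv @ u + sigma2_e * np.trace(Ginv @ Cuu)) / q
            e = y - X @ b - u[phen_idx]
            new_e = float(y @ (w * e)) / (n - p)
            if new_e <= 0 or new_g <= 0:
                converged = False
                break
            rel = max(abs(new_g - sigma2_g) / sigma2_g,
                      abs(new_e - sigma2_e) / sigma2_e)
            sigma2_g, sigma2_e = float(new_g), float(new_e)
            if rel < reml_tol:
                break
        else:
            converged = False
            warnings.warn("EM-REML did not converge; using last iterate")

    lam = sigma2_e / sigma2_g
    sol, resid, _ = _mme_solve(X, y, w, Ginv * lam, phen_idx, q)
    b, u = sol[:p], sol[p:]
    return GBLUPFit(
        fixed_effects=pd.Series(b, index=names),
        gebv=pd.Series(u, index=list(grm.animal_ids)),
        sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e), lam=float(lam),
        solver_residual=float(resid), reml_converged=converged,
    )


def fit_wgblup_traits(
    drp_list: list,
    grm: GRM,
    params: WeightParams | None = None,
    sigma2_g: float = 1.0,
    sigma2_e: float | None = None,
    ridge: float = 1e-6,
) -> list:
    """Weighted GBLUP for several traits sharing animals and weights.

    Record and daughter counts do not depend on the trait, so the tables
    share the design matrix and the residual weight structure; the
    coefficient matrix is assembled and factorized once and solved for each
    trait's right-hand side. Fixed variance components only (one lambda).
    """
    first = drp_list[0]
    for d in drp_list[1:]:
        if (not np.array_equal(d.animal_ids, first.animal_ids)
                or not np.allclose(d.weight, first.weight)):
            raise ValueError("traits must share animals and weights; "
                             "fit separately otherwise")
    if params is None:
        params = WeightParams()
    if sigma2_e is None:
        sigma2_e = sigma2_g * (1.0 - params.h2) / params.h2
    lam = sigma2_e / sigma2_g

    q = len(grm.animal_ids)
    phen_idx = grm.animal_index(first.animal_ids)
    X, names = build_design_matrix(first.sex, first.breed_group)
    p = X.shape[1]
    w = first.weight

    G = grm.matrix.copy()
    if ridge:
        G[np.diag_indices_from(G)] += ridge
    cf_G = linalg.cho_factor(G, lower=True, check_finite=False)
    Ginv = linalg.cho_solve(cf_G, np.eye(q), check_finite=False)
    Ginv = 0.5 * (Ginv + Ginv.T)

    D = w
    C = np.zeros((p + q, p + q))
    C[:p, :p] = X.T @ (X * D[:, None])
    ZtDX = np.zeros((q, p))
    ZtDX[phen_idx] = X * D[:, None]
    C[:p, p:] = ZtDX.T
    C[p:, :p] = ZtDX
    C[p:, p:] = Ginv * lam
    C[p + phen_idx, p + phen_idx] += D
    cf = linalg.cho_factor(C, lower=True, check_finite=False)

    fits = []
    for d in drp_list:
        rhs = np.zeros(p + q)
        rhs[:p] = X.T @ (D * d.y)
        rhs[p + phen_idx] = D * d.y
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        resid = np.max(np.abs(C @ sol - rhs))
        fits.append(GBLUPFit(
            fixed_effects=pd.Series(sol[:p], index=names),
            gebv=pd.Series(sol[p:], index=list(grm.animal_ids)),
            sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e),
            lam=float(lam), solver_residual=float(resid),
        ))
    return fits
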