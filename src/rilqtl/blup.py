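"""REML/BLUP evaluation of a line panel in incomplete blocks with checks.

The model is y = Xt + Zg + Wb + e with experiment effects t fixed,
genotype effects g ~ N(0, s2g I), block effects b ~ N(0, s2b I) and
residuals e ~ N(0, s2e I), all mutually independent with homogeneous
variances.  Variance components are estimated by EM-REML on Henderson's
mixed-model equations; genotypic values are mu + g_hat (BLUP), with
prediction error variance PEV from the inverse coefficient matrix,
SEP = sqrt(PEV), selective accuracy sqrt(1 - PEV/s2g), and broad-sense
heritability h2 = s2g / (s2g + s2b + s2e).  Common check genotypes enter
the model as ordinary (random) genotypes; they are what connects
experiments, so a connectivity check runs before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PanelDesign",
    "MixedModelResult",
    "PanelMixedModel",
    "fit_mixed_model",
    "genotypic_ci",
    "compare_genotypes",
]

_VAR_FLOOR = 1e-10


@dataclass
class PanelDesign:
    """Plot records of a line panel: genotype, experiment, block, value.

    Blocks are incomplete blocks nested within experiments; the block
    factor used by the model is the (experiment, block) combination.
    """

    data: pd.DataFrame

    REQUIRED = ("genotype", "experiment", "block", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel design missing columns: {missing}")
        df = self.data.dropna(subset=["value"])
        if df.empty:
            raise ValueError("panel design has no usable records")
        self.data = df.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path) -> "PanelDesign":
        return cls(pd.read_csv(path, comment="#"))

    def connectivity_groups(self) -> list[set]:
        """Connected components of the genotype-experiment bipartite graph."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        genos = pd.Categorical(self.data["genotype"])
        exps = pd.Categorical(self.data["experiment"])
        ng, ne = len(genos.categories), len(exps.categories)
        row = np.concatenate([genos.codes, exps.codes + ng])
        col = np.concatenate([exps.codes + ng, genos.codes])
        adj = coo_matrix((np.ones(len(row)), (row, col)), shape=(ng + ne, ng + ne))
        n_comp, labels = connected_components(adj, directed=False)
        groups = []
        for comp in range(n_comp):
            members = {
                genos.categories[i] for i in range(ng) if labels[i] == comp
            }
            if members:
                groups.append(members)
        return groups


class PanelMixedModel:
    """Mixed model y = Xt + Zg + Wb + e for a genotype panel.

    Build from a tidy plot table with :meth:`from_dataframe` (columns
    genotype, experiment, block, value) and call :meth:`fit` for EM-REML
    estimates, BLUPs and their prediction-error variances.
    """

    def __init__(self, design: PanelDesign):
        df = design.data
        self.design = design
        self.genotypes = pd.Categorical(df["genotype"])
        self.experiments = pd.Categorical(df["experiment"])
        block_key = df["experiment"].astype(str) + ":" + df["block"].astype(str)
        self.blocks = pd.Categorical(block_key)
        self.y = df["value"].to_numpy(dtype=float)
        self.n = len(self.y)
        self.q = len(self.genotypes.categories)
        self.t = len(self.experiments.categories)
        self.b = len(self.blocks.categories)
        if self.q < 2:
            raise ValueError("at least 2 genotypes are required")
        groups = design.connectivity_groups()
        if len(groups) > 1:
            named = "; ".join(
                "{" + ", ".join(sorted(map(str, g))[:5]) + ("...}" if len(g) > 5 else "}")
                for g in groups
            )
            raise ValueError(
                f"design is disconnected across experiments ({len(groups)} groups): {named}"
            )
        self.X = self._dummies(self.experiments, self.t)
        self.Z = self._dummies(self.genotypes, self.q)
        self.W = self._dummies(self.blocks, self.b)

    @staticmethod
    def _dummies(cat: pd.Categorical, k: int) -> np.ndarray:
        out = np.zeros((len(cat), k))
        out[np.arange(len(cat)), cat.codes] = 1.0
        return out

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value: str = "value",
        genotype: str = "genotype",
        experiment: str = "experiment",
        block: str = "block",
    ) -> "PanelMixedModel":
        renamed = df.rename(
            columns={value: "value", genotype: "genotype",
                     experiment: "experiment", block: "block"}
        )
        return cls(PanelDesign(renamed[["genotype", "experiment", "block", "value"]]))

    # -- fitting ---------------------------------------------------------
    def _neg2_reml(self, s2g: float, s2b: float, s2e: float) -> float:
        """-2 x restricted log-likelihood (up to a constant) at given components."""
        from scipy.linalg import cho_factor, cho_solve

        X, Z, W, y = self.X, self.Z, self.W, self.y
        V = s2e * np.eye(self.n) + s2g * (Z @ Z.T) + s2b * (W @ W.T)
        cf = cho_factor(V, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vi_y = cho_solve(cf, y)
        vi_x = cho_solve(cf, X)
        xtvix = X.T @ vi_x
        sign, logdet_x = np.linalg.slogdet(xtvix)
        beta = np.linalg.lstsq(xtvix, X.T @ vi_y, rcond=None)[0]
        quad = float(y @ vi_y - (X.T @ vi_y) @ beta)
        return logdet_v + logdet_x + quad

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> "MixedModelResult":
        """REML fit: maximize the restricted likelihood over the variance
        components (bounded at zero), then solve Henderson's mixed-model
        equations at the estimates for BLUPs and prediction-error variances.
        """
        from scipy import optimize

        X, Z, W, y = self.X, self.Z, self.W, self.y
        n, t, q, b = self.n, self.t, self.q, self.b
        vy = float(np.var(y, ddof=1)) or 1.0
        XtX, XtZ, XtW = X.T @ X, X.T @ Z, X.T @ W
        ZtZ, ZtW, WtW = Z.T @ Z, Z.T @ W, W.T @ W
        rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])

        floor_e = _VAR_FLOOR * vy

        def objective(params):
            return self._neg2_reml(params[0], params[1], max(params[2], floor_e))

        opt = optimize.minimize(
            objective,
            x0=np.array([vy / 3, vy / 3, vy / 3]),
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (floor_e, None)],
            options={"maxiter": max_iter, "ftol": tol},
        )
        at_floor = opt.x[2] <= floor_e * 1.5  # perfect-fit boundary: likelihood unbounded
        if not opt.success and not at_floor:
            # polish with a derivative-free restart before giving up
            opt2 = optimize.minimize(
                objective, x0=np.maximum(opt.x, 0),
                method="Nelder-Mead",
                bounds=[(0.0, None), (0.0, None), (floor_e, None)],
                options={"maxiter": 2000, "fatol": tol, "xatol": 1e-10},
            )
            if opt2.fun <= opt.fun:
                opt = opt2
        if not np.all(np.isfinite(opt.x)) or not np.isfinite(opt.fun):
            raise RuntimeError(
                f"REML optimisation failed after {opt.nit} iterations: {opt.message}; "
                f"trace: components {opt.x}, -2logL {opt.fun:.6g}"
            )
        s2g, s2b, s2e = opt.x
        s2g, s2b = max(s2g, 0.0), max(s2b, 0.0)
        s2e = max(s2e, floor_e)
        # prune directions the likelihood is flat in (e.g. a block factor
        # fully confounded with the mean): a component whose removal does
        # not worsen the restricted likelihood is set to zero
        base = objective([s2g, s2b, s2e])
        tol_prune = 1e-4 * max(1.0, abs(base))  # -2logL differences below this are noise
        if s2b > 0 and objective([s2g, 0.0, s2e]) <= base + tol_prune:
            s2b = 0.0
        if s2g > 0 and objective([0.0, s2b, s2e]) <= base + tol_prune:
            s2g = 0.0
        it = int(opt.nit)
        converged = bool(opt.success) or opt.x[2] <= floor_e * 1.5
        # solve the mixed-model equations at the REML estimates
        lam_g = s2e / max(s2g, _VAR_FLOOR * vy)
        lam_b = s2e / max(s2b, _VAR_FLOOR * vy)
        C = np.block(
            [
                [XtX, XtZ, XtW],
                [XtZ.T, ZtZ + lam_g * np.eye(q), ZtW],
                [XtW.T, ZtW.T, WtW + lam_b * np.eye(b)],
            ]
        )
        Cinv = np.linalg.pinv(C)
        sol = Cinv @ rhs
        beta, g_hat = sol[:t], sol[t:t + q]
        mu = float(np.mean(beta))
        # PEV of the predicted genotypic value mu + g_i: contrast of the
        # average experiment effect plus the genotype effect, so the
        # uncertainty that is inseparable between mu and mean(g) cancels
        # instead of inflating every genotype
        K = np.zeros((q, t + q + b))
        K[:, :t] = 1.0 / t
        K[np.arange(q), t + np.arange(q)] = 1.0
        pev = np.maximum(s2e * np.einsum("ij,jk,ik->i", K, Cinv, K), 0.0)
        if s2g <= _VAR_FLOOR * vy:
            accuracy = np.zeros(q)
        else:
            accuracy = np.sqrt(np.clip(1.0 - pev / s2g, 0.0, 1.0))
        h2 = s2g / (s2g + s2b + s2e)
        return MixedModelResult(
            sigma2_g=float(s2g),
            sigma2_b=float(s2b),
            sigma2_e=float(s2e),
            fixed_effects=pd.Series(beta, index=list(self.experiments.categories),
                                    name="experiment_mean"),
            mu=mu,
            genotype_ids=list(self.genotypes.categories),
            blup=g_hat,
            pev=pev,
            accuracy=accuracy,
            h2=float(h2),
            n_iter=it,
            converged=converged,
            n_records=n,
        )


@dataclass
class MixedModelResult:
    """REML variance components, BLUPs and their precision for a panel."""

    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    fixed_effects: pd.Series
    mu: float
    genotype_ids: list
    blup: np.ndarray
    pev: np.ndarray
    accuracy: np.ndarray
    h2: float
    n_iter: int
    converged: bool
    n_records: int

    @property
    def sep(self) -> np.ndarray:
        """Standard error of prediction: sqrt(PEV)."""
        return np.sqrt(self.pev)

    @property
    def genotypic_values(self) -> pd.Series:
        return pd.Series(self.mu + self.blup, index=self.genotype_ids,
                         name="genotypic_value")

    def per_genotype(self, t_value: float = 1.96) -> pd.DataFrame:
        gv = self.mu + self.blup
        return pd.DataFrame(
            {
                "genotype": self.genotype_ids,
                "blup": self.blup,
                "genotypic_value": gv,
                "pev": self.pev,
                "sep": self.sep,
                "ci_lo": gv - t_value * self.sep,
                "ci_hi": gv + t_value * self.sep,
                "accuracy": self.accuracy,
            }
        )

    def summary(self) -> str:
        lines = [
            "Mixed-model REML/BLUP panel evaluation",
            f"  records            : {self.n_records}",
            f"  genotypes          : {len(self.genotype_ids)}",
            f"  sigma2_g           : {self.sigma2_g:.4f}",
            f"  sigma2_b           : {self.sigma2_b:.4f}",
            f"  sigma2_e           : {self.sigma2_e:.4f}",
            f"  broad-sense h2     : {self.h2:.3f}",
            f"  mean accuracy      : {float(np.mean(self.accuracy)):.3f}",
            f"  EM iterations      : {self.n_iter}",
        ]
        return "\n".join(lines)


def fit_mixed_model(design: PanelDesign | pd.DataFrame, **kwargs) -> MixedModelResult:
    """Fit the panel mixed model from a PanelDesign or tidy DataFrame."""
    if isinstance(design, pd.DataFrame):
        design = PanelDesign(design)
    return PanelMixedModel(design).fit(**kwargs)


def genotypic_ci(result: MixedModelResult, t_value: float = 1.96) -> pd.DataFrame:
    """Per-genotype confidence intervals (mu + g) +/- t x SEP."""
    return result.per_genotype(t_value=t_value)[
        ["genotype", "genotypic_value", "ci_lo", "ci_hi"]
    ]


def compare_genotypes(cis: pd.DataFrame) -> pd.DataFrame:
    """Pairwise significance by CI overlap: disjoint (strictly) = significant.

    Closed intervals: touching endpoints count as overlap, hence not
    significant.  Input needs genotype, ci_lo, ci_hi columns; the result
    is a boolean genotype x genotype matrix.
    """
    ids = cis["genotype"].tolist()
    lo = cis["ci_lo"].to_numpy(dtype=float)
    hi = cis["ci_hi"].to_numpy(dtype=float)
    disjoint = (lo[:, None] > hi[None, :]) | (hi[:, None] < lo[None, :])
    return pd.DataFrame(disjoint, index=ids, columns=ids)
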