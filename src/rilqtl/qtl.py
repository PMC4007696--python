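"""QTL and eQTL mapping by single-marker regression and stepwise multi-SNP models.

The mapping engine regresses a line-level trait on allele-indicator coded
markers (A=0, H=0.5, B=1), so a fitted coefficient is the difference
between the two homozygote classes.  A forward stepwise search adds, at
each round, the marker with the smallest partial-F p-value conditional on
the current model, stopping when that p-value reaches the significance
threshold (default p < 0.001, with no genome-wide multiple-testing
correction — the declared-QTL count therefore carries the pointwise
false-positive rate of the greedy search, which the property tests
document).  Variance explained is partitioned by nested residual sums of
squares: R2_P = 1 - SSE(full)/SSE(reduced) for each selected SNP, and
R2_T = 1 - SSE(full)/SST for the whole model.  Peak positions are the
markers with the highest -log10(P); support intervals come from a
1-unit drop in the conditional -log10(P) curve, with a case-resampling
bootstrap as an alternative.

Dense marker coverage in a RIL population makes observed marker genotypes
stand in for QTL genotypes directly, so no hidden-genotype probabilities
are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix

__all__ = [
    "QtlResults",
    "EpistasisResult",
    "StepwiseQtlModel",
    "single_marker_scan",
    "stepwise_multi_snp",
    "partial_r2",
    "total_r2",
    "epistasis_scan",
    "qtl_interval",
    "report_qtls",
]

_LN10 = np.log(10.0)
_COLLINEAR_TOL = 1e-9


def _trait_vector(geno: GenotypeMatrix, trait) -> np.ndarray:
    """Align a trait to geno.lines -> float vector with NaN for absent lines."""
    if isinstance(trait, pd.DataFrame):
        if not {"line", "value"} <= set(trait.columns):
            raise ValueError("trait DataFrame needs 'line' and 'value' columns")
        trait = trait.set_index("line")["value"]
    if isinstance(trait, pd.Series):
        return trait.reindex(geno.lines).to_numpy(dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (geno.n_lines,):
        raise ValueError(
            f"trait length {arr.shape} does not match {geno.n_lines} lines"
        )
    return arr


def _neglog10_from_t(t: np.ndarray, dof) -> np.ndarray:
    """-log10 of the two-sided t-test p-value, stable for huge |t|."""
    with np.errstate(invalid="ignore"):
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), dof)
    return -logp / _LN10


def _partial_regression(X, y, Q, dof):
    """Slope/t/-log10p of y on each X column, given covariate basis Q.

    X columns must be NaN-free; Q is an orthonormal basis (n x p) of the
    covariate space (including the intercept).  Returns (beta, nlp, ok)
    where ok flags columns with usable (non-collinear) variation.
    """
    RX = X - Q @ (Q.T @ X)
    ry = y - Q @ (Q.T @ y)
    sxx = np.einsum("ij,ij->j", RX, RX)
    sxy = RX.T @ ry
    syy = float(ry @ ry)
    ok = sxx > _COLLINEAR_TOL
    beta = np.full(X.shape[1], np.nan)
    nlp = np.full(X.shape[1], np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    sse = syy - beta[ok] * sxy[ok]
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] * np.sqrt(sxx[ok] * dof / np.where(sse > 0, sse, np.nan))
        t = np.where(sse > 0, t, np.inf * np.sign(beta[ok]))
    nlp[ok] = _neglog10_from_t(t, dof)
    return beta, nlp, ok


def _conditional_scan(geno, y, covariate_idx, candidate_idx=None):
    """Per-marker slope and -log10 p conditional on covariate markers.

    Lines with missing trait or missing covariate genotype are dropped for
    the whole scan; markers with residual missingness are fitted on their
    own complete cases.  Returns (beta, nlp, n_used) over candidate_idx.
    """
    D = geno.dosage()
    if candidate_idx is None:
        candidate_idx = np.arange(geno.n_markers)
    C = D[:, covariate_idx] if len(covariate_idx) else np.empty((geno.n_lines, 0))
    rows = np.isfinite(y) & np.isfinite(C).all(axis=1)
    n0 = int(rows.sum())
    p_cov = C.shape[1]
    beta = np.full(len(candidate_idx), np.nan)
    nlp = np.full(len(candidate_idx), np.nan)
    n_used = np.zeros(len(candidate_idx), dtype=int)
    if n0 < p_cov + 3:
        return beta, nlp, n_used
    X = D[np.ix_(rows, candidate_idx)]
    yr = y[rows]
    Dsn = np.column_stack([np.ones(n0), C[rows]])
    Q, _ = np.linalg.qr(Dsn)
    dof = n0 - p_cov - 2
    complete = np.isfinite(X).all(axis=0)
    if dof >= 1 and complete.any():
        b, nl, ok = _partial_regression(X[:, complete], yr, Q, dof)
        beta[complete] = b
        nlp[complete] = nl
        n_used[complete] = n0
    # markers with their own missingness: individual complete-case fits
    for j in np.flatnonzero(~complete):
        x = X[:, j]
        sub = np.isfinite(x)
        n_j = int(sub.sum())
        if n_j < p_cov + 3:
            continue
        Dj = np.column_stack([np.ones(n_j), C[rows][sub]])
        Qj, Rj = np.linalg.qr(Dj)
        if np.abs(np.diag(Rj)).min() < 1e-10:
            continue
        b, nl, ok = _partial_regression(x[sub, None], yr[sub], Qj, n_j - p_cov - 2)
        if ok[0]:
            beta[j], nlp[j], n_used[j] = b[0], nl[0], n_j
    return beta, nlp, n_used


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def single_marker_scan(geno: GenotypeMatrix, trait) -> pd.DataFrame:
    """Per-marker OLS of trait on the allele indicator {0, 0.5, 1}.

    Two-sided p from the t distribution on n-2 df; markers with fewer
    than 3 informative lines, or with a constant genotype column, get
    missing results.  Returns marker, chrom, pos, effect, neglog10p, n.
    """
    y = _trait_vector(geno, trait)
    beta, nlp, n_used = _conditional_scan(geno, y, covariate_idx=[])
    out = geno.markers[["marker", "chrom", "pos"]].copy()
    out["effect"] = beta
    out["neglog10p"] = nlp
    out["n"] = n_used
    return out


def _model_rows(geno, y, idx):
    D = geno.dosage()
    M = D[:, idx] if len(idx) else np.empty((geno.n_lines, 0))
    rows = np.isfinite(y) & np.isfinite(M).all(axis=1)
    return D, rows


def _sse(X, y):
    """Residual sum of squares of y on [1, X] via least squares."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def partial_r2(geno: GenotypeMatrix, trait, model_markers, focal_marker) -> float:
    """R2_P % for one SNP: 100 x (1 - SSE(full)/SSE(reduced)).

    The reduced model contains all other selected markers; both models are
    fitted on the lines complete across the full model.
    """
    if focal_marker not in list(model_markers):
        raise ValueError(f"focal marker {focal_marker!r} not in model")
    y = _trait_vector(geno, trait)
    idx = geno.marker_indices(model_markers)
    D, rows = _model_rows(geno, y, idx)
    X = D[np.ix_(rows, idx)]
    yr = y[rows]
    sse_full, _ = _sse(X, yr)
    keep = [m != focal_marker for m in model_markers]
    sse_red, _ = _sse(X[:, keep], yr)
    if sse_red <= 0:
        warnings.warn("reduced model already has zero residual SSE; R2_P defined as 0")
        return 0.0
    return 100.0 * (1.0 - sse_full / sse_red)


def total_r2(geno: GenotypeMatrix, trait, model_markers) -> float:
    """R2_T %: variance explained by the full model against intercept-only."""
    y = _trait_vector(geno, trait)
    idx = geno.marker_indices(model_markers)
    D, rows = _model_rows(geno, y, idx)
    yr = y[rows]
    sse_full, _ = _sse(D[np.ix_(rows, idx)], yr)
    sst = float(np.sum((yr - yr.mean()) ** 2))
    if sst <= 0:
        return 0.0
    return 100.0 * (1.0 - sse_full / sst)


def qtl_interval(
    geno: GenotypeMatrix,
    trait,
    model_markers,
    focal_marker,
    drop: float = 1.0,
    method: str = "drop",
    n_boot: int = 200,
    seed: int | None = None,
) -> dict:
    """Peak position and support/confidence interval for one QTL, in Mbp.

    All markers on the focal chromosome are rescanned conditional on the
    other model markers.  ``method='drop'``: the interval spans the
    markers whose conditional -log10 p is within ``drop`` units of the
    peak.  ``method='bootstrap'``: lines are resampled with replacement,
    the conditional peak re-located each time, and the 2.5/97.5 percentile
    positions reported.
    """
    if method not in ("drop", "bootstrap"):
        raise ValueError("method must be 'drop' or 'bootstrap'")
    model_markers = list(model_markers)
    if focal_marker not in model_markers:
        raise ValueError(f"focal marker {focal_marker!r} not in model")
    y = _trait_vector(geno, trait)
    focal_idx = int(geno.marker_indices([focal_marker])[0])
    chrom = int(geno.markers["chrom"].iloc[focal_idx])
    cand = np.flatnonzero(geno.markers["chrom"].to_numpy() == chrom)
    cov_idx = geno.marker_indices([m for m in model_markers if m != focal_marker])
    beta, nlp, n_used = _conditional_scan(geno, y, cov_idx, cand)
    usable = ~np.isnan(nlp)
    if not usable.any():
        raise ValueError("conditional scan produced no usable p-values on the focal chromosome")
    pos = geno.markers["pos"].to_numpy()[cand]
    peak_local = int(np.argmax(np.where(usable, nlp, -np.inf)))
    peak_nlp = nlp[peak_local]
    peak_mbp = pos[peak_local] / 1e6
    if method == "drop":
        inside = usable & (nlp >= peak_nlp - drop)
        lo, hi = pos[inside].min() / 1e6, pos[inside].max() / 1e6
    else:
        rng = np.random.default_rng(seed)
        D = geno.dosage()
        C = D[:, cov_idx] if len(cov_idx) else np.empty((geno.n_lines, 0))
        rows = np.flatnonzero(np.isfinite(y) & np.isfinite(C).all(axis=1))
        chrom_markers = geno.markers.iloc[cand].reset_index(drop=True)
        peaks = []
        for _ in range(n_boot):
            bs = rng.choice(rows, size=rows.size, replace=True)
            gsub = GenotypeMatrix(
                [f"b{i}" for i in range(len(bs))], chrom_markers.copy(),
                geno.calls[bs][:, cand],
            )
            # adjust the resampled trait for the off-focal model markers,
            # then scan the focal chromosome unconditionally
            yb = y[bs]
            if len(cov_idx):
                Cb = C[bs]
                okb = np.isfinite(yb) & np.isfinite(Cb).all(axis=1)
                _, coef = _sse(Cb[okb], yb[okb])
                yb = yb - np.column_stack([np.ones(len(bs)), Cb]) @ coef
            _, nlpb, _ = _conditional_scan(gsub, yb, [], np.arange(len(cand)))
            usable_b = ~np.isnan(nlpb)
            if usable_b.any():
                pk = int(np.argmax(np.where(usable_b, nlpb, -np.inf)))
                peaks.append(pos[pk])
        if not peaks:
            raise ValueError("bootstrap produced no usable peaks")
        lo, hi = np.percentile(peaks, [2.5, 97.5]) / 1e6
    lo = min(lo, peak_mbp)
    hi = max(hi, peak_mbp)
    return {"chrom": chrom, "peak_mbp": float(peak_mbp), "ci_lo_mbp": float(lo),
            "ci_hi_mbp": float(hi), "peak_neglog10p": float(peak_nlp)}


@dataclass
class EpistasisResult:
    """Pairwise interaction tests: full model + one product term at a time."""

    n_pairs_eligible: int
    n_pairs_tested: int
    pairs: pd.DataFrame  # marker1, marker2, effect, neglog10p
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        nlp_thr = -np.log10(self.alpha)
        sig = self.pairs[self.pairs["neglog10p"] > nlp_thr]
        return sig.reset_index(drop=True)


def epistasis_scan(
    geno: GenotypeMatrix, trait, model_markers, alpha: float = 0.001
) -> EpistasisResult:
    """Test all pairwise interactions among model SNPs and model x other SNPs.

    For each eligible pair the additive model over all selected SNPs is
    augmented with the product of the pair's allele indicators; the
    product term's partial-F (equivalently t) p-value is reported.  With
    k model SNPs of m total, k(k-1)/2 + k(m-k) pairs are eligible;
    degenerate product columns are skipped and counted as untested.
    """
    model_markers = list(model_markers)
    k = len(model_markers)
    if k == 0:
        raise ValueError("epistasis scan requires a non-empty model")
    y = _trait_vector(geno, trait)
    idx = geno.marker_indices(model_markers)
    D, rows = _model_rows(geno, y, idx)
    n0 = int(rows.sum())
    M = D[np.ix_(rows, idx)]
    yr = y[rows]
    design = np.column_stack([np.ones(n0), M])
    Q, _ = np.linalg.qr(design)
    dof = n0 - (k + 1) - 1
    m = geno.n_markers
    eligible = k * (k - 1) // 2 + k * (m - k)
    records = []
    n_tested = 0
    if dof >= 1:
        # model x model
        for a in range(k):
            for b in range(a + 1, k):
                z = (M[:, a] * M[:, b])[:, None]
                beta, nlp, ok = _partial_regression(z, yr, Q, dof)
                if ok[0]:
                    n_tested += 1
                    records.append((model_markers[a], model_markers[b], beta[0], nlp[0]))
        # model x all other markers
        other = np.setdiff1d(np.arange(m), idx)
        names = geno.markers["marker"].to_numpy()
        Xo = D[np.ix_(rows, other)]
        complete = np.isfinite(Xo).all(axis=0)
        for a in range(k):
            Z = Xo[:, complete] * M[:, a][:, None]
            beta, nlp, ok = _partial_regression(Z, yr, Q, dof)
            n_tested += int(ok.sum())
            sel = np.flatnonzero(ok)
            for t, j in zip(sel, other[complete][sel]):
                records.append((model_markers[a], names[j], beta[t], nlp[t]))
            # markers with residual missingness: individual fits
            for j in other[~complete]:
                x = D[rows, j]
                sub = np.isfinite(x)
                n_j = int(sub.sum())
                if n_j < k + 4:
                    continue
                Dj = np.column_stack([np.ones(n_j), M[sub]])
                Qj, Rj = np.linalg.qr(Dj)
                if np.abs(np.diag(Rj)).min() < 1e-10:
                    continue
                z = (x[sub] * M[sub, a])[:, None]
                beta, nlp, ok = _partial_regression(z, yr[sub], Qj, n_j - (k + 1) - 1)
                if ok[0]:
                    n_tested += 1
                    records.append((model_markers[a], names[j], beta[0], nlp[0]))
    pairs = pd.DataFrame(records, columns=["marker1", "marker2", "effect", "neglog10p"])
    return EpistasisResult(
        n_pairs_eligible=eligible, n_pairs_tested=n_tested, pairs=pairs, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Stepwise model / results objects
# ---------------------------------------------------------------------------

class StepwiseQtlModel:
    """Forward stepwise multi-SNP regression model for a line-level trait.

    Parameters
    ----------
    geno : GenotypeMatrix
    trait : Series/DataFrame/array
        Line-level trait values; Series indexed by line or DataFrame with
        line/value columns.
    alpha : float
        Entry threshold on the conditional (partial-F) p-value; the search
        stops when the best remaining marker's p >= alpha.
    """

    def __init__(self, geno: GenotypeMatrix, trait, alpha: float = 0.001):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.geno = geno
        self.trait = trait
        self.alpha = alpha
        self._y = _trait_vector(geno, trait)

    def fit(
        self,
        epistasis: bool = False,
        ci_method: str = "drop",
        ci_drop: float = 1.0,
        n_boot: int = 200,
        seed: int | None = None,
        max_qtls: int = 25,
    ) -> "QtlResults":
        geno, y, alpha = self.geno, self._y, self.alpha
        markers = geno.markers
        chroms = markers["chrom"].to_numpy()
        poss = markers["pos"].to_numpy()
        names = markers["marker"].to_numpy()
        nlp_thr = -np.log10(alpha)

        scan0 = single_marker_scan(geno, y)
        selected: list[int] = []
        while len(selected) < max_qtls:
            cand = np.setdiff1d(np.arange(geno.n_markers), selected)
            if cand.size == 0:
                break
            beta, nlp, n_used = _conditional_scan(geno, y, selected, cand)
            usable = ~np.isnan(nlp)  # +inf = exact fit, still selectable
            if not usable.any():
                break
            # best p first; ties broken by smallest (chrom, bp)
            order = np.lexsort((poss[cand], chroms[cand], -nlp))
            best = order[0]
            # add only while the best conditional p-value is strictly below alpha
            if not usable[best] or nlp[best] <= nlp_thr:
                break
            selected.append(int(cand[best]))

        sel_names = [names[j] for j in selected]
        qtl_rows = []
        if selected:
            D, rows = _model_rows(geno, y, np.array(selected))
            X = D[np.ix_(rows, selected)]
            yr = y[rows]
            A = np.column_stack([np.ones(len(yr)), X])
            coef, _, _, _ = np.linalg.lstsq(A, yr, rcond=None)
            resid = yr - A @ coef
            sse = float(resid @ resid)
            dof = len(yr) - A.shape[1]
            XtX_inv = np.linalg.pinv(A.T @ A)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(np.maximum(np.diag(XtX_inv), 0) * sse / max(dof, 1))
                tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
            nlp_cond = _neglog10_from_t(tvals[1:], max(dof, 1))
            scan_by_name = scan0.set_index("marker")
            for pos_in_model, j in enumerate(selected):
                name = names[j]
                ci = qtl_interval(
                    geno, y, sel_names, name, drop=ci_drop,
                    method=ci_method, n_boot=n_boot, seed=seed,
                )
                qtl_rows.append(
                    {
                        "marker": name,
                        "chrom": int(chroms[j]),
                        "pos": int(poss[j]),
                        "position_mbp": ci["peak_mbp"],
                        "effect": float(coef[1 + pos_in_model]),
                        "neglog10p_conditional": float(nlp_cond[pos_in_model]),
                        "neglog10p_marginal": float(scan_by_name.loc[name, "neglog10p"]),
                        "r2_partial_pct": partial_r2(geno, y, sel_names, name),
                        "ci_lo_mbp": ci["ci_lo_mbp"],
                        "ci_hi_mbp": ci["ci_hi_mbp"],
                        "n": int(len(yr)),
                    }
                )
        qtls = pd.DataFrame(
            qtl_rows,
            columns=[
                "marker", "chrom", "pos", "position_mbp", "effect",
                "neglog10p_conditional", "neglog10p_marginal",
                "r2_partial_pct", "ci_lo_mbp", "ci_hi_mbp", "n",
            ],
        )
        r2t = total_r2(geno, y, sel_names) if sel_names else 0.0
        epi = epistasis_scan(geno, y, sel_names, alpha) if (epistasis and sel_names) else None
        return QtlResults(
            model=self, scan=scan0, qtls=qtls, r2_total=float(r2t),
            epistasis=epi, alpha=alpha,
        )


@dataclass
class QtlResults:
    """Fitted stepwise QTL model: selected SNPs, effects, R2 partition, CIs."""

    model: StepwiseQtlModel
    scan: pd.DataFrame
    qtls: pd.DataFrame
    r2_total: float
    epistasis: EpistasisResult | None
    alpha: float

    @property
    def selected_markers(self) -> list[str]:
        return self.qtls["marker"].tolist()

    def declared_qtls(self) -> pd.DataFrame:
        """Model SNPs grouped into declared QTL regions.

        A SNP is declared only if it stays significant (conditional
        p < alpha) in the final multi-SNP model: forward-only selection
        never removes an early proxy pick that a later, better tag of the
        same region renders redundant, but such a SNP is not a QTL the
        model supports.  Declared SNPs on the same chromosome are then
        merged into one region when their support intervals overlap or
        one SNP's peak lies inside the other's interval.  Each region is
        represented by its most significant SNP (conditional -log10 P),
        whose effect, R2_P and interval are reported, with
        ``n_model_snps`` recording how many SNPs the region absorbed.
        """
        nlp_thr = -np.log10(self.alpha)
        df = self.qtls[self.qtls["neglog10p_conditional"] > nlp_thr].reset_index(drop=True)
        if df.empty:
            out = df.copy()
            out["n_model_snps"] = pd.Series(dtype=int)
            return out
        parent = list(range(len(df)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        rows = df.to_dict("records")
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a["chrom"] != b["chrom"]:
                    continue
                overlap = a["ci_lo_mbp"] <= b["ci_hi_mbp"] and b["ci_lo_mbp"] <= a["ci_hi_mbp"]
                inside = (
                    a["ci_lo_mbp"] <= b["position_mbp"] <= a["ci_hi_mbp"]
                    or b["ci_lo_mbp"] <= a["position_mbp"] <= b["ci_hi_mbp"]
                )
                if overlap or inside:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(rows)):
            groups.setdefault(find(i), []).append(i)
        reps = []
        for members in groups.values():
            best = max(members, key=lambda i: rows[i]["neglog10p_conditional"])
            rep = dict(rows[best])
            rep["n_model_snps"] = len(members)
            reps.append(rep)
        out = pd.DataFrame(reps).sort_values(["chrom", "pos"]).reset_index(drop=True)
        return out

    def report(self, trait_name: str = "ALT", merge_regions: bool = True) -> pd.DataFrame:
        return report_qtls(self, trait_name, merge_regions=merge_regions)

    def summary(self) -> str:
        lines = [
            f"Stepwise multi-SNP QTL model (alpha = {self.alpha:g})",
            f"  selected SNPs : {len(self.qtls)}",
            f"  total R2      : {self.r2_total:.2f} %",
        ]
        for row in self.qtls.itertuples(index=False):
            lines.append(
                f"  {row.marker:<16} chr{row.chrom:<3} {row.position_mbp:8.2f} Mbp  "
                f"effect {row.effect:8.2f}  -log10P {row.neglog10p_conditional:6.2f}  "
                f"R2P {row.r2_partial_pct:5.2f} %  "
                f"CI {row.ci_lo_mbp:.2f} - {row.ci_hi_mbp:.2f}"
            )
        if self.epistasis is not None:
            lines.append(
                f"  epistasis     : {len(self.epistasis.significant)} significant of "
                f"{self.epistasis.n_pairs_tested} tested pairs"
            )
        return "\n".join(lines)

    def plot_scan(self, ax=None):
        """Manhattan-style plot of the single-marker scan."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        for c, sub in self.scan.groupby("chrom"):
            ax.scatter(offset + sub["pos"] / 1e6, sub["neglog10p"], s=4,
                       color="C0" if c % 2 else "C1", rasterized=True)
            offset += sub["pos"].max() / 1e6 + 5
        ax.axhline(-np.log10(self.alpha), color="grey", ls="--", lw=1)
        ax.set_xlabel("genome position (Mbp, chromosomes concatenated)")
        ax.set_ylabel("-log10 P")
        return ax


def stepwise_multi_snp(geno: GenotypeMatrix, trait, alpha: float = 0.001, **fit_kwargs) -> QtlResults:
    """Functional entry point: fit the forward stepwise multi-SNP model."""
    return StepwiseQtlModel(geno, trait, alpha=alpha).fit(**fit_kwargs)


def report_qtls(
    results: QtlResults, trait_name: str = "ALT", merge_regions: bool = True
) -> pd.DataFrame:
    """QTL report table: one row per declared QTL, named q{TRAIT}{chr}.

    With ``merge_regions`` (default) model SNPs tagging one region are
    collapsed via :meth:`QtlResults.declared_qtls`; otherwise every model
    SNP gets a row.  Columns: qtl, snp_id, chrom, position_mbp,
    neglog10p, effect, r2_partial_pct, ci; total R2 % is stored in
    ``attrs['r2_total_pct']``.  Repeated regions on one chromosome get a
    ``.2``, ``.3`` ... suffix.
    """
    source = results.declared_qtls() if merge_regions else results.qtls.assign(n_model_snps=1)
    rows = []
    seen: dict[int, int] = {}
    for row in source.itertuples(index=False):
        seen[row.chrom] = seen.get(row.chrom, 0) + 1
        name = f"q{trait_name}{row.chrom}"
        if seen[row.chrom] > 1:
            name += f".{seen[row.chrom]}"
        rows.append(
            {
                "qtl": name,
                "snp_id": row.marker,
                "chrom": row.chrom,
                "position_mbp": round(row.position_mbp, 2),
                "neglog10p": round(row.neglog10p_conditional, 2),
                "neglog10p_marginal": round(row.neglog10p_marginal, 2),
                "effect": round(row.effect, 2),
                "r2_partial_pct": round(row.r2_partial_pct, 2),
                "ci": f"{row.ci_lo_mbp:.2f} - {row.ci_hi_mbp:.2f}",
                "n_model_snps": int(row.n_model_snps),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "qtl", "snp_id", "chrom", "position_mbp", "neglog10p",
            "neglog10p_marginal", "effect", "r2_partial_pct", "ci",
            "n_model_snps",
        ],
    )
    out.attrs["r2_total_pct"] = round(results.r2_total, 2)
    out.attrs["trait"] = trait_name
    return out
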