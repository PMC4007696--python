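"""Synthetic data generation for a biparental RIL mapping study.

The generator emulates the structure of a maize Al-tolerance experiment:
118 recombinant inbred lines at the S7 selfing generation genotyped at
dense GBS-style SNPs over 10 chromosomes, phenotyped for relative net root
growth in a completely randomized design with 2 replicates and 7 plants
per plot, with 5 additive QTLs, GBS-like missingness, chromosome-specific
segregation distortion, line-level expression traits driven by cis/trans
eQTLs, and qPCR Ct tables for ddCT expression/copy-number quantification.

Meiosis uses the Haldane map function (crossovers Poisson in map distance,
no interference): between adjacent markers separated by d cM a gamete
switches parental haplotype with probability r = (1 - exp(-2d/100))/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix
from .pheno import PhenotypeTable
from .qpcr import QpcrTable

__all__ = [
    "GeneticMap",
    "QtlSpec",
    "EqtlSpec",
    "DEFAULT_QTL_EFFECTS",
    "maize_like_map",
    "simulate_ril_genomes",
    "simulate_phenotypes",
    "simulate_expression",
    "degrade_genotypes",
    "simulate_qpcr",
]

# Additive QTL effects (trait units, RNRG %) and positions used as the
# package's reference 5-QTL architecture: chromosomes 2, 3, 5, 6, 8.
DEFAULT_QTL_EFFECTS = [
    (2, 212_940_514, 9.14),
    (3, 187_460_236, 13.11),
    (5, 30_301_926, 9.82),
    (6, 5_860_000, 14.21),
    (8, 22_681_622, 10.43),
]

# Approximate maize chromosome spans (Mbp), chromosomes 1..10.
_MAIZE_SPANS_MBP = [301, 237, 232, 242, 217, 169, 177, 175, 157, 150]


@dataclass
class GeneticMap:
    """Per-chromosome marker positions on genetic (cM) and physical (bp) scales.

    ``cm[c]`` is nondecreasing, ``bp[c]`` strictly increasing and 1-based;
    both have equal length with at least one marker per chromosome.
    """

    cm: dict[int, np.ndarray]
    bp: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if not self.cm:
            raise ValueError("empty genetic map")
        if set(self.cm) != set(self.bp):
            raise ValueError("cm and bp cover different chromosomes")
        for c in self.cm:
            cm = np.asarray(self.cm[c], dtype=float)
            bp = np.asarray(self.bp[c], dtype=np.int64)
            if cm.size == 0 or cm.size != bp.size:
                raise ValueError(f"chromosome {c}: cm/bp lengths invalid")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"chromosome {c}: cM positions must be nondecreasing")
            if (np.diff(bp) <= 0).any() or (bp < 1).any():
                raise ValueError(f"chromosome {c}: bp positions must be strictly increasing, 1-based")
            self.cm[c], self.bp[c] = cm, bp

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.cm)

    @classmethod
    def uniform(
        cls, spans_cm, markers_per_chromosome: int, mbp_per_cm: float = 1.0
    ) -> "GeneticMap":
        """Evenly spaced markers; physical positions scale cM by ``mbp_per_cm``."""
        cm, bp = {}, {}
        for i, span in enumerate(spans_cm, start=1):
            pos_cm = np.linspace(0.0, float(span), markers_per_chromosome)
            pos_bp = np.round(pos_cm * mbp_per_cm * 1e6).astype(np.int64) + 1
            pos_bp = np.maximum.accumulate(pos_bp + np.arange(len(pos_bp)))  # strict
            cm[i], bp[i] = pos_cm, pos_bp
        return cls(cm=cm, bp=bp)

    def marker_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chromosomes:
            for p in self.bp[c]:
                rows.append({"marker": f"S{c}_{p}", "chrom": c, "pos": int(p)})
        return pd.DataFrame(rows)


def maize_like_map(markers_per_chromosome: int = 2000) -> GeneticMap:
    """Ten chromosomes with maize-like spans, 1 cM ~ 1 Mbp."""
    return GeneticMap.uniform(_MAIZE_SPANS_MBP, markers_per_chromosome)


@dataclass
class QtlSpec:
    """Additive QTL architecture for a plot-structured trait.

    ``qtls``: list of (chromosome, bp position, effect in trait units) —
    the effect is the difference between the two homozygote classes, with
    the second (B / tolerant) parent's allele coded 1.  Exactly one of
    ``residual_variance`` (plot-level error variance) or ``heritability``
    (target family-mean h2, solved via h2 = s2g / (s2g + s2e/r) at the
    realized genetic variance) must be given.
    """

    qtls: list[tuple[int, int, float]]
    residual_variance: float | None = None
    heritability: float | None = None
    replicates: int = 2
    plants_per_plot: int = 7
    baseline: float = 30.0

    def __post_init__(self) -> None:
        if (self.residual_variance is None) == (self.heritability is None):
            raise ValueError("set exactly one of residual_variance / heritability")
        if self.heritability is not None and not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1)")
        if self.residual_variance is not None and self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.plants_per_plot < 1:
            raise ValueError("plants_per_plot must be >= 1")


@dataclass
class EqtlSpec:
    """Line-level expression architecture: eQTLs as variance fractions.

    ``eqtls``: list of (chromosome, bp, fraction of expression variance);
    fractions lie in (0, 1) and sum to < 1, the remainder being noise.
    """

    eqtls: list[tuple[int, int, float]]
    baseline: float = 1.0
    noise_variance: float = 1.0

    def __post_init__(self) -> None:
        fr = [f for _, _, f in self.eqtls]
        if any(not 0 < f < 1 for f in fr):
            raise ValueError("variance fractions must be in (0, 1)")
        if sum(fr) >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


# ---------------------------------------------------------------------------
# RIL genome simulation
# ---------------------------------------------------------------------------

def _meiosis(haplos: np.ndarray, r_adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from (n, 2, m) haplotypes; r_adj: (m-1,) switch probs."""
    n, _, m = haplos.shape
    start = rng.integers(0, 2, size=(n, 1))
    if m > 1:
        switches = rng.random((n, m - 1)) < r_adj
        which = (start + np.concatenate([np.zeros((n, 1), bool), np.cumsum(switches, axis=1)], axis=1)) % 2
    else:
        which = start
    return np.take_along_axis(haplos, which[:, None, :].astype(np.int64), axis=1)[:, 0, :]


def simulate_ril_genomes(
    gmap: GeneticMap, n_lines: int, n_self_generations: int, seed: int
) -> GenotypeMatrix:
    """Simulate RIL genotypes by selfing from a fully heterozygous F1.

    Each of ``n_self_generations`` rounds forms two independent gametes per
    line (Haldane model, no interference) and unites them.  Calls are A/B
    for the two parental homozygotes and H for residual heterozygosity,
    which decays as (1/2)^g.
    """
    if n_lines < 1 or n_self_generations < 1:
        raise ValueError("n_lines and n_self_generations must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory for reproducible simulation")
    rng = np.random.default_rng(seed)
    chrom_calls = []
    for c in gmap.chromosomes:
        cm = gmap.cm[c]
        m = len(cm)
        d = np.diff(cm)
        r_adj = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        haplos = np.zeros((n_lines, 2, m), dtype=np.int8)
        haplos[:, 1, :] = 1  # F1: one haplotype from each parent
        for _ in range(n_self_generations):
            g1 = _meiosis(haplos, r_adj, rng)
            g2 = _meiosis(haplos, r_adj, rng)
            haplos = np.stack([g1, g2], axis=1)
        chrom_calls.append((haplos[:, 0, :] + haplos[:, 1, :]).astype(np.int8))
    calls = np.concatenate(chrom_calls, axis=1)
    lines = [f"RIL-{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(lines=lines, markers=gmap.marker_frame(), calls=calls)


def _resolve_qtl_markers(geno: GenotypeMatrix, qtls) -> pd.DataFrame:
    """Snap each (chrom, bp, effect) to the nearest marker on its chromosome."""
    chroms = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()
    rows = []
    for chrom, bp, effect in qtls:
        on_c = np.flatnonzero(chroms == chrom)
        if on_c.size == 0:
            raise ValueError(f"QTL chromosome {chrom} absent from genotype map")
        p = pos[on_c]
        if not p.min() <= bp <= p.max():
            raise ValueError(
                f"QTL position {bp} outside chromosome {chrom} span [{p.min()}, {p.max()}]"
            )
        j = on_c[np.argmin(np.abs(p - bp))]
        rows.append(
            {
                "marker": geno.markers["marker"].iloc[j],
                "chrom": int(chrom),
                "pos": int(pos[j]),
                "requested_bp": int(bp),
                "effect": float(effect),
                "index": int(j),
            }
        )
    return pd.DataFrame(rows)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    spec: QtlSpec,
    seed: int,
    control_nrg_mean: float = 6.0,
    control_nrg_sd: float = 0.5,
    initial_root_length: float = 4.0,
) -> PhenotypeTable:
    """Simulate plot-level root-growth phenotypes under control and Al.

    The genetic value of a line is baseline + sum over QTLs of
    effect x allele indicator (0 / 0.5 / 1 for A / H / B); plot values add
    N(0, s2e) noise at the plot-mean level (plants within a plot are
    collapsed).  Plots are emitted as (line, rep, treatment, IRL, FRL)
    records such that 100 x NRG_Al / NRG_c per (line, rep) reproduces the
    simulated trait value exactly; the trait is on the RNRG percent scale.

    Returns a :class:`~rilqtl.pheno.PhenotypeTable` whose
    ``causal_markers`` attribute tags the markers carrying the QTLs.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    causal = _resolve_qtl_markers(geno, spec.qtls)
    dose = geno.dosage()[:, causal["index"].to_numpy()]
    dose = np.nan_to_num(dose, nan=0.5)  # missing causal call: average allele
    gvals = spec.baseline + dose @ causal["effect"].to_numpy()

    if spec.residual_variance is not None:
        s2e = float(spec.residual_variance)
    else:
        s2g = float(np.var(gvals, ddof=1))
        h2 = spec.heritability
        s2e = spec.replicates * s2g * (1.0 - h2) / h2

    r = spec.replicates
    n = geno.n_lines
    rows = []
    for rep in range(1, r + 1):
        nrg_c = control_nrg_mean + rng.normal(0.0, control_nrg_sd, size=n)
        nrg_c = np.maximum(nrg_c, 0.5)
        trait = gvals + rng.normal(0.0, np.sqrt(s2e), size=n)
        nrg_al = nrg_c * trait / 100.0
        for i, line in enumerate(geno.lines):
            rows.append((line, rep, "control", initial_root_length,
                         initial_root_length + nrg_c[i]))
            rows.append((line, rep, "Al", initial_root_length,
                         initial_root_length + nrg_al[i]))
    df = pd.DataFrame(rows, columns=["line", "rep", "treatment", "irl", "frl"])
    table = PhenotypeTable(df)
    table.causal_markers = causal.drop(columns="index")
    return table


def simulate_expression(
    geno: GenotypeMatrix, spec: EqtlSpec, seed: int
) -> pd.DataFrame:
    """Simulate a line-level expression trait driven by eQTLs.

    Each eQTL's effect size is back-solved from its target variance
    fraction using the realized dosage variance at its marker, so the
    realized fractions match the requested values up to sampling error.  Returns a
    tidy frame (line, value) with causal markers in ``attrs['causal_markers']``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    causal = _resolve_qtl_markers(geno, [(c, p, f) for c, p, f in spec.eqtls])
    fracs = causal["effect"].to_numpy()  # variance fractions here
    # with zero noise the total variance is set to 1 (arbitrary units) and
    # the trait is exactly the genetic value: degenerate but useful
    if spec.noise_variance > 0:
        total_var = spec.noise_variance / (1.0 - fracs.sum())
    else:
        total_var = 1.0
    dose = geno.dosage()[:, causal["index"].to_numpy()]
    dose = np.nan_to_num(dose, nan=0.5)
    betas = np.empty(len(fracs))
    for j, f in enumerate(fracs):
        vd = np.var(dose[:, j], ddof=1)
        if vd <= 0:
            raise ValueError(f"eQTL marker {causal['marker'].iloc[j]} is monomorphic")
        betas[j] = np.sqrt(f * total_var / vd)
    values = spec.baseline + dose @ betas + rng.normal(
        0.0, np.sqrt(spec.noise_variance), size=geno.n_lines
    )
    out = pd.DataFrame({"line": geno.lines, "value": values})
    causal = causal.drop(columns="index").rename(columns={"effect": "variance_fraction"})
    causal["beta"] = betas
    out.attrs["causal_markers"] = causal
    return out


def degrade_genotypes(
    geno: GenotypeMatrix,
    missing_rate: float,
    seed: int,
    distorted_chromosome: int | None = None,
    distortion_allele_freq: float = 0.5,
) -> GenotypeMatrix:
    """Apply GBS-like degradation: i.i.d. missingness and segregation distortion.

    On the distorted chromosome each line's founder assignment is
    re-weighted — with the appropriate probability the whole chromosome is
    replaced by the over-represented parent's homozygote — so the B-allele
    frequency is approximately ``distortion_allele_freq``.  Missingness is
    then applied i.i.d. at ``missing_rate``.
    """
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    if not 0 < distortion_allele_freq < 1:
        raise ValueError("distortion_allele_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)
    calls = geno.calls.copy()
    if distorted_chromosome is not None:
        cols = np.flatnonzero(geno.markers["chrom"].to_numpy() == distorted_chromosome)
        if cols.size == 0:
            raise ValueError(f"chromosome {distorted_chromosome} not in genotype matrix")
        q = distortion_allele_freq
        if q <= 0.5:
            w, fill = 1.0 - 2.0 * q, 0  # favour parent A
        else:
            w, fill = 2.0 * q - 1.0, 2  # favour parent B
        replace = rng.random(geno.n_lines) < w
        calls[np.ix_(replace, cols)] = fill
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    return GenotypeMatrix(list(geno.lines), geno.markers.copy(), calls)


# ---------------------------------------------------------------------------
# qPCR fixture generation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_copy_number: dict[str, float] | None = None,
    true_expression_ratio: dict[str, float] | None = None,
    efficiency: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    calibrator: str | None = None,
    n_replicates: int = 3,
    assays: tuple[str, ...] | None = None,
    reference_ct: float = 20.0,
) -> QpcrTable:
    """Generate a Ct table consistent with ddCT quantification.

    Under 100% efficiency the target Ct shifts by -log2(quantity ratio)
    relative to the reference; a general per-cycle amplification factor of
    (1 + efficiency) is supported.  Exactly one of ``true_copy_number``
    (role 'cnv', default assays CNV2/CNV4) or ``true_expression_ratio``
    (role 'expression') is given, mapping sample id -> true quantity
    relative to the calibrator (which must be present with value 1).
    """
    if (true_copy_number is None) == (true_expression_ratio is None):
        raise ValueError("set exactly one of true_copy_number / true_expression_ratio")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    role = "cnv" if true_copy_number is not None else "expression"
    quantities = dict(true_copy_number or true_expression_ratio)
    if calibrator is None:
        calibrator = next(iter(quantities))
    if calibrator not in quantities:
        raise ValueError(f"calibrator {calibrator!r} missing from sample quantities")
    if any(q <= 0 for q in quantities.values()):
        raise ValueError("quantities must be positive")
    if assays is None:
        assays = ("CNV2", "CNV4") if role == "cnv" else ("EXPR",)
    rng = np.random.default_rng(seed)
    base = np.log(1.0 + efficiency) / np.log(2.0)  # cycles per doubling equivalent
    rows = []
    for sample, q in quantities.items():
        rel = q / quantities[calibrator]
        for assay in assays:
            for rep in range(1, n_replicates + 1):
                ct_ref = reference_ct + rng.normal(0.0, noise_sd)
                ct_tgt = (
                    reference_ct
                    - np.log2(rel) / base
                    + rng.normal(0.0, noise_sd)
                )
                rows.append((sample, assay, rep, ct_tgt, ct_ref))
    df = pd.DataFrame(
        rows, columns=["sample", "assay", "replicate", "ct_target", "ct_reference"]
    )
    return QpcrTable(data=df, calibrator=calibrator, role=role)
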