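"""Genotype containers, I/O, marker QC, imputation and introgression analysis.

Genotypes from a biparental RIL population are held as a lines x markers
call matrix over {A, H, B, missing}: A = homozygous for the first parent's
allele, B = homozygous for the second parent's allele, H = heterozygous.
Markers carry genomic coordinates (chromosome, 1-based bp) and identifiers
of the form ``S{chr}_{bp}``, the convention used for GBS-derived SNPs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CALL_CODES",
    "CODE_TO_CALL",
    "GenotypeMatrix",
    "FilterReport",
    "IntrogressionResult",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "filter_markers",
    "segregation_distortion",
    "impute_missing",
    "detect_introgression",
    "read_gff3_genes",
    "genes_in_interval",
]

# Integer codes used in the call matrix.  -1 = missing ("N" on disk).
CALL_CODES = {"A": 0, "H": 1, "B": 2, "N": -1}
CODE_TO_CALL = {v: k for k, v in CALL_CODES.items()}

_SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files; carries offending line numbers."""


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype call matrix with genomic coordinates.

    Parameters
    ----------
    lines : list of str
        Line identifiers (rows of ``calls``).
    markers : pandas.DataFrame
        One row per marker with columns ``marker`` (unique ID), ``chrom``
        (int) and ``pos`` (1-based bp, int), sorted by (chrom, pos).
    calls : ndarray of int8, shape (n_lines, n_markers)
        Coded calls: 0=A, 1=H, 2=B, -1=missing.
    """

    lines: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        ids = self.markers["marker"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise GenotypeFormatError(f"duplicate marker IDs: {dups[:5]}")
        self._validate_ids()
        self._ensure_sorted()

    # -- invariants ------------------------------------------------------
    def _validate_ids(self) -> None:
        for marker, chrom, pos in self.markers[["marker", "chrom", "pos"]].itertuples(
            index=False
        ):
            m = _SNP_ID_RE.match(str(marker))
            if m and (int(m.group(1)) != int(chrom) or int(m.group(2)) != int(pos)):
                raise GenotypeFormatError(
                    f"marker ID {marker!r} disagrees with chrom={chrom}, pos={pos}"
                )

    def _ensure_sorted(self) -> None:
        order = np.lexsort((self.markers["pos"].to_numpy(), self.markers["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            warnings.warn("markers were not sorted by (chrom, pos); auto-sorting")
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]

    # -- basic accessors -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.markers["chrom"].unique().tolist())

    def line_index(self, line: str) -> int:
        try:
            return self.lines.index(line)
        except ValueError:
            raise KeyError(f"unknown line {line!r}") from None

    def dosage(self) -> np.ndarray:
        """Allele-indicator coding: A=0, H=0.5, B=1, missing=NaN (float64)."""
        d = self.calls.astype(np.float64) / 2.0
        d[self.calls < 0] = np.nan
        return d

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls < 0).mean(axis=0)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            lines=list(self.lines),
            markers=self.markers.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
        )

    def marker_indices(self, names) -> np.ndarray:
        idx = pd.Index(self.markers["marker"])
        locs = idx.get_indexer(list(names))
        if (locs < 0).any():
            missing = [n for n, l in zip(names, locs) if l < 0]
            raise KeyError(f"unknown markers: {missing}")
        return locs

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.lines), self.markers.copy(), self.calls.copy())


# ---------------------------------------------------------------------------
# I/O: HapMap-style TSV (rs#, chrom, pos, line1..lineN), calls A/B/H/N
# ---------------------------------------------------------------------------

def read_genotypes(path) -> GenotypeMatrix:
    """Read a HapMap-style tab-separated genotype file.

    Leading lines starting with ``#`` are treated as comments.  Malformed
    data rows are reported with their (1-based) file line numbers.
    """
    header = None
    markers = []
    rows = []
    bad: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if len(header) < 4:
                    raise GenotypeFormatError(
                        f"line {lineno}: header needs >=4 columns (rs#, chrom, pos, lines)"
                    )
                continue
            if len(fields) != len(header):
                bad.append((lineno, "wrong number of columns"))
                continue
            marker, chrom, pos = fields[0], fields[1], fields[2]
            try:
                chrom_i, pos_i = int(chrom), int(pos)
            except ValueError:
                bad.append((lineno, f"non-integer chrom/pos: {chrom!r}/{pos!r}"))
                continue
            calls = fields[3:]
            unknown = sorted({c for c in calls if c not in CALL_CODES})
            if unknown:
                bad.append((lineno, f"invalid calls {unknown}"))
                continue
            markers.append((marker, chrom_i, pos_i))
            rows.append([CALL_CODES[c] for c in calls])
    if header is None:
        raise GenotypeFormatError("empty genotype file")
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:10])
        raise GenotypeFormatError(f"{len(bad)} malformed row(s): {detail}")
    marker_df = pd.DataFrame(markers, columns=["marker", "chrom", "pos"])
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(header) - 3, 0), np.int8)
    return GenotypeMatrix(lines=list(header[3:]), markers=marker_df, calls=calls)


def write_genotypes(geno: GenotypeMatrix, path, header_comments=()) -> None:
    """Write a GenotypeMatrix as HapMap-style TSV (lossless round-trip)."""
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(["rs#", "chrom", "pos", *geno.lines]) + "\n")
        chroms = geno.markers["chrom"].to_numpy()
        poss = geno.markers["pos"].to_numpy()
        names = geno.markers["marker"].to_numpy()
        for j in range(geno.n_markers):
            calls = (CODE_TO_CALL[int(c)] for c in geno.calls[:, j])
            fh.write(
                "\t".join([str(names[j]), str(chroms[j]), str(poss[j]), *calls]) + "\n"
            )


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def minor_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF from non-missing calls; H counts half to each allele."""
    n_a = (geno.calls == 0).sum(axis=0)
    n_b = (geno.calls == 2).sum(axis=0)
    n_h = (geno.calls == 1).sum(axis=0)
    a = 2 * n_a + n_h
    b = 2 * n_b + n_h
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, np.minimum(a, b) / np.where(tot > 0, tot, 1), 0.0)
    return maf.astype(float)


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_markers`: counts removed by each rule.

    ``per_chromosome`` has one row per chromosome with columns
    input / removed_missing / removed_monomorphic / removed_maf / retained.
    Invariant: removed + retained = input, per chromosome and in total.
    """

    max_missing_fraction: float
    maf_thresholds: dict
    per_chromosome: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.per_chromosome.drop(columns="chrom").sum()

    def __str__(self) -> str:
        t = self.totals
        return (
            f"FilterReport: {int(t['input'])} markers in, {int(t['retained'])} retained "
            f"({int(t['removed_missing'])} >= {self.max_missing_fraction:.0%} missing, "
            f"{int(t['removed_monomorphic'])} monomorphic, "
            f"{int(t['removed_maf'])} below MAF threshold)"
        )


def filter_markers(
    geno: GenotypeMatrix,
    max_missing_fraction: float = 0.20,
    maf_default: float = 0.40,
    maf_per_chromosome: dict | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers by missingness and minor allele frequency.

    A marker is retained iff its missing fraction is strictly below
    ``max_missing_fraction`` AND its MAF is at or above the threshold for
    its chromosome (``maf_per_chromosome`` overrides ``maf_default``, e.g.
    ``{10: 0.3}`` to relax chromosome 10 under segregation distortion).
    """
    if not 0 <= maf_default <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    maf_per_chromosome = dict(maf_per_chromosome or {})
    for thr in maf_per_chromosome.values():
        if not 0 <= thr <= 0.5:
            raise ValueError("per-chromosome MAF threshold must be in [0, 0.5]")

    miss = geno.missing_fraction()
    maf = minor_allele_frequency(geno)
    chroms = geno.markers["chrom"].to_numpy()
    thr = np.array([maf_per_chromosome.get(int(c), maf_default) for c in chroms])

    fail_missing = miss >= max_missing_fraction
    monomorphic = (~fail_missing) & (maf == 0)
    fail_maf = (~fail_missing) & (~monomorphic) & (maf < thr)
    keep = ~(fail_missing | monomorphic | fail_maf)

    rows = []
    for c in geno.chromosomes:
        sel = chroms == c
        rows.append(
            {
                "chrom": c,
                "input": int(sel.sum()),
                "removed_missing": int(fail_missing[sel].sum()),
                "removed_monomorphic": int(monomorphic[sel].sum()),
                "removed_maf": int(fail_maf[sel].sum()),
                "retained": int(keep[sel].sum()),
            }
        )
    report = FilterReport(
        max_missing_fraction=max_missing_fraction,
        maf_thresholds={int(c): maf_per_chromosome.get(int(c), maf_default) for c in geno.chromosomes},
        per_chromosome=pd.DataFrame(rows),
    )
    return geno.subset_markers(keep), report


def segregation_distortion(geno: GenotypeMatrix) -> pd.DataFrame:
    """Chi-square test of 1:1 segregation on homozygote counts, per marker.

    Heterozygous and missing calls are excluded; 1 df, no continuity
    correction.  Returns columns marker, chrom, pos, n_a, n_b, chi2, p.
    """
    from scipy import stats

    n_a = (geno.calls == 0).sum(axis=0).astype(float)
    n_b = (geno.calls == 2).sum(axis=0).astype(float)
    tot = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(tot > 0, (n_a - n_b) ** 2 / np.where(tot > 0, tot, 1), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(chi2 == 0, 1.0, p)
    out = geno.markers[["marker", "chrom", "pos"]].copy()
    out["n_a"] = n_a.astype(int)
    out["n_b"] = n_b.astype(int)
    out["chi2"] = chi2
    out["p"] = p
    return out


# ---------------------------------------------------------------------------
# k-NN imputation (sliding window of flanking markers)
# ---------------------------------------------------------------------------

def impute_missing(
    geno: GenotypeMatrix, window_halfwidth: int = 10, k_neighbors: int = 5
) -> GenotypeMatrix:
    """Fill missing calls by majority vote among the k nearest lines.

    For each missing call the k lines with the smallest mismatch fraction
    to the focal line — over non-missing calls within ``window_halfwidth``
    markers on either side, same chromosome — vote with their (non-missing)
    call at the focal marker.  Observed calls are never altered; a call is
    left missing only when no informative neighbour exists.
    """
    if window_halfwidth < 1 or k_neighbors < 1:
        raise ValueError("window_halfwidth and k_neighbors must be >= 1")
    out = geno.calls.copy()
    chroms = geno.markers["chrom"].to_numpy()
    n_lines = geno.n_lines
    all_missing_markers = []
    for c in np.unique(chroms):
        cols = np.flatnonzero(chroms == c)
        C = geno.calls[:, cols]  # (n_lines, m_c) view for this chromosome
        m_c = C.shape[1]
        valid = C >= 0
        for jj in np.flatnonzero(~valid.all(axis=0)):
            lo, hi = max(0, jj - window_halfwidth), min(m_c, jj + window_halfwidth + 1)
            W = C[:, lo:hi]
            Wv = valid[:, lo:hi]
            focal_missing = np.flatnonzero(~valid[:, jj])
            has_call = valid[:, jj]
            if not has_call.any():
                all_missing_markers.append(geno.markers["marker"].iloc[cols[jj]])
                continue
            # mismatch fraction between each missing line and every line
            diff = (W[focal_missing, None, :] != W[None, :, :]) & (
                Wv[focal_missing, None, :] & Wv[None, :, :]
            )
            overlap = (Wv[focal_missing, None, :] & Wv[None, :, :]).sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(overlap > 0, diff.sum(axis=2) / np.maximum(overlap, 1), np.inf)
            for t, i in enumerate(focal_missing):
                d = dist[t].copy()
                d[i] = np.inf  # self
                d[~has_call] = np.inf  # neighbour must vote
                d[overlap[t] == 0] = np.inf  # no shared information
                finite = np.flatnonzero(np.isfinite(d))
                if finite.size == 0:
                    continue
                k = min(k_neighbors, finite.size)
                nn = finite[np.argpartition(d[finite], k - 1)[:k]]
                votes = np.bincount(C[nn, jj], minlength=3)
                out[i, cols[jj]] = int(np.argmax(votes))
    if all_missing_markers:
        warnings.warn(
            f"{len(all_missing_markers)} marker(s) entirely missing; left unimputed"
        )
    return GenotypeMatrix(list(geno.lines), geno.markers.copy(), out)


# ---------------------------------------------------------------------------
# NIL introgression analysis
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionResult:
    """Donor genome segments detected in a near-isogenic line.

    ``segments``: one row per donor segment with chrom, start_bp, end_bp,
    length_mbp.  ``recovery_pct``: recurrent-parent allele fraction across
    informative markers genome-wide, in percent.
    """

    segments: pd.DataFrame
    recovery_pct: float
    n_informative: int


def detect_introgression(
    geno: GenotypeMatrix,
    nil: str,
    donor: str,
    recurrent: str,
    boundary: str = "midpoint",
) -> IntrogressionResult:
    """Locate donor-parent segments in a NIL relative to its two parents.

    Informative markers are those where donor and recurrent parents are
    homozygous for different alleles.  Donor segments are maximal runs of
    informative markers at which the NIL carries the donor homozygote.
    With ``boundary='midpoint'`` segment ends are placed halfway between
    the outermost donor-allele marker and its flanking recurrent-allele
    marker (segment ends at the run's own markers when there is no flank);
    ``boundary='outermost'`` uses the donor markers' own positions.
    """
    if boundary not in ("midpoint", "outermost"):
        raise ValueError("boundary must be 'midpoint' or 'outermost'")
    i_nil = geno.line_index(nil)
    i_don = geno.line_index(donor)
    i_rec = geno.line_index(recurrent)
    c_nil, c_don, c_rec = (geno.calls[i] for i in (i_nil, i_don, i_rec))

    informative = (
        np.isin(c_don, (0, 2)) & np.isin(c_rec, (0, 2)) & (c_don != c_rec)
    )
    # NIL must itself be homozygous at a marker to assign parental origin
    scorable = informative & np.isin(c_nil, (0, 2))
    if not scorable.any():
        raise ValueError("no informative markers between donor and recurrent parents")

    is_donor = scorable & (c_nil == c_don)
    is_recur = scorable & (c_nil == c_rec)
    recovery = 100.0 * is_recur.sum() / scorable.sum()

    chroms = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()
    seg_rows = []
    for c in np.unique(chroms):
        idx = np.flatnonzero((chroms == c) & scorable)
        if idx.size == 0:
            continue
        donor_flags = is_donor[idx]
        p = pos[idx]
        j = 0
        while j < idx.size:
            if not donor_flags[j]:
                j += 1
                continue
            j0 = j
            while j + 1 < idx.size and donor_flags[j + 1]:
                j += 1
            start, end = float(p[j0]), float(p[j])
            if boundary == "midpoint":
                if j0 > 0:
                    start = (p[j0 - 1] + p[j0]) / 2.0
                if j + 1 < idx.size:
                    end = (p[j] + p[j + 1]) / 2.0
            seg_rows.append(
                {
                    "chrom": int(c),
                    "start_bp": start,
                    "end_bp": end,
                    "length_mbp": (end - start) / 1e6,
                }
            )
            j += 1
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start_bp", "end_bp", "length_mbp"])
    return IntrogressionResult(
        segments=segments, recovery_pct=float(recovery), n_informative=int(scorable.sum())
    )


# ---------------------------------------------------------------------------
# Candidate-gene interval queries
# ---------------------------------------------------------------------------

def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into (gene_id, chrom, start, end)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        chrom = int(re.sub(r"^chr", "", str(feat.seqid), flags=re.IGNORECASE))
        rows.append({"gene_id": gid, "chrom": chrom, "start": feat.start, "end": feat.end})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def genes_in_interval(
    annotation: pd.DataFrame,
    interval: tuple[int, int, int],
    significant_snps=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes overlapping a (chrom, start, end) interval, and the subset covered.

    Coordinates are 1-based closed intervals; overlap is inclusive on both
    ends.  A gene is "covered" iff at least one significant SNP position
    lies within its span.  ``significant_snps`` is an iterable of
    (chrom, pos) pairs or a DataFrame with chrom/pos columns.
    """
    chrom, start, end = interval
    if annotation.empty:
        empty = annotation.copy()
        return empty, empty.copy()
    hit = (
        (annotation["chrom"] == chrom)
        & (annotation["start"] <= end)
        & (annotation["end"] >= start)
    )
    genes = annotation.loc[hit].reset_index(drop=True)
    if significant_snps is None:
        snp = np.empty((0, 2), dtype=int)
    elif isinstance(significant_snps, pd.DataFrame):
        snp = significant_snps[["chrom", "pos"]].to_numpy()
    else:
        snp = np.asarray(list(significant_snps), dtype=int).reshape(-1, 2)
    pos_on_chrom = snp[snp[:, 0] == chrom, 1] if snp.size else np.array([], dtype=int)
    covered_mask = [
        bool(((pos_on_chrom >= s) & (pos_on_chrom <= e)).any())
        for s, e in genes[["start", "end"]].itertuples(index=False)
    ]
    covered = genes.loc[covered_mask].reset_index(drop=True) if len(genes) else genes.copy()
    return genes, covered
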