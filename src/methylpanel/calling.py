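"""Methylation calling from barcoded bisulfite amplicon reads.

Re-implements the four-stage amplicon pipeline: (i) split reads per sample
by exact barcode prefix match, (ii) trim the barcode, (iii) assign each read
to a panel amplicon under bisulfite-aware matching, and (iv) filter reads by
bisulfite conversion rate and call the methylation status (1/0/missing) of
every CpG site, then aggregate calls into a per-sample methylation matrix
with a read-depth retention rule.

Bisulfite-aware matching treats every reference cytosine as ambiguous
(read C or T both match: T is the converted state, C is either methylation
at a CpG or a conversion failure elsewhere); all other bases must match
exactly. Reads are tried in both orientations (a reverse read is the
reverse complement of the converted top strand) against each amplicon of
matching length, ungapped: the amplicons are short (129-260 bp) so reads
span the full reference and indel-containing reads simply fail assignment.

The read-level conversion filter uses the fraction of non-CpG reference
cytosines read as T; reads below the minimum conversion rate (default 0.97,
inclusive) are discarded from calling. The region-level coverage filter
retains a measurement (one sample x amplicon mean methylation) when the
binomial standard deviation sqrt(p(1-p)/n) of its mean gives either a
coefficient of variation below 5% or an absolute SD of at most 1% — the SD
branch rescues very small methylation percentages for which the CV rule is
too stringent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import Amplicon

_C, _T = ord("C"), ord("T")
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b

DEFAULT_MIN_CONVERSION = 0.97
DEFAULT_MAX_MISMATCH_FRAC = 0.10
DEFAULT_CV_THRESHOLD = 0.05
DEFAULT_SD_THRESHOLD = 0.01


class CallingConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRef:
    """Precomputed arrays for bisulfite-aware matching of one amplicon."""

    gene: str
    ref: np.ndarray          # uint8 reference bases
    is_c: np.ndarray         # bool: reference base is C (any context)
    cpg0: np.ndarray         # 0-based offsets of CpG cytosines
    noncpg_c0: np.ndarray    # 0-based offsets of non-CpG cytosines

    @property
    def length(self) -> int:
        return self.ref.size


def build_references(panel: list[Amplicon]) -> list[AmpliconRef]:
    refs = []
    for amp in panel:
        arr = np.frombuffer(amp.sequence.encode(), dtype=np.uint8)
        cpg0 = np.array([p - 1 for p in amp.cpg_positions], dtype=int)
        is_c = arr == _C
        noncpg = np.where(is_c & ~np.isin(np.arange(arr.size), cpg0))[0]
        refs.append(AmpliconRef(amp.gene, arr, is_c, cpg0, noncpg))
    return refs


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    return _COMP_LUT[mat][:, ::-1]


def _mismatch_counts(mat: np.ndarray, ref: AmpliconRef) -> np.ndarray:
    """Per-row mismatch count of a read matrix against one reference,
    with C/T ambiguity at every reference cytosine."""
    ok = (mat == ref.ref) | (ref.is_c & ((mat == _C) | (mat == _T)))
    return (~ok).sum(axis=1)


# ---------------------------------------------------------------------------
# (i)-(ii) demultiplexing and trimming
# ---------------------------------------------------------------------------

def demultiplex(
    reads: list[tuple[str, str]],
    sample_sheet: pd.DataFrame,
    adaptor_len: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], int]:
    """Group reads by sample barcode (exact prefix match after skipping
    ``adaptor_len`` leading bases) and trim adaptor+barcode off.

    Returns ``(groups, n_unassigned)`` with one (possibly empty) group per
    library in the sample sheet.
    """
    barcodes = sample_sheet["barcode"].astype(str)
    if barcodes.duplicated().any():
        raise CallingConfigError("duplicate barcodes in sample sheet")
    if barcodes.str.len().nunique() > 1:
        raise CallingConfigError("barcodes must have equal length")
    bc_len = int(barcodes.str.len().iloc[0]) if len(barcodes) else 0
    by_bc = dict(zip(barcodes, sample_sheet["library_id"]))
    groups: dict[str, list[tuple[str, str]]] = {
        lib: [] for lib in sample_sheet["library_id"]
    }
    unassigned = 0
    for read_id, seq in reads:
        bc = seq[adaptor_len:adaptor_len + bc_len]
        lib = by_bc.get(bc)
        if lib is None:
            unassigned += 1
        else:
            groups[lib].append((read_id, seq[adaptor_len + bc_len:]))
    return groups, unassigned


# ---------------------------------------------------------------------------
# (iii) amplicon assignment
# ---------------------------------------------------------------------------

def assign_to_amplicon(
    seq: str,
    refs: list[AmpliconRef],
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[str, str, int, int] | None:
    """Assign one trimmed read to its best (amplicon, orientation).

    Returns ``(gene, orientation, mismatches, n_ties)`` or None when the
    best candidate exceeds the mismatch-fraction threshold (or no amplicon
    has the read's length). Ties go to the first amplicon in panel order.
    """
    mat = np.frombuffer(seq.encode(), dtype=np.uint8)[None, :]
    best: tuple[int, int, str] | None = None  # (mismatches, ref_index, orientation)
    ties = 0
    for idx, ref in enumerate(refs):
        if ref.length != mat.shape[1]:
            continue
        for orientation, m in (
            ("forward", mat),
            ("reverse", _revcomp_rows(mat)),
        ):
            mm = int(_mismatch_counts(m, ref)[0])
            if best is None or mm < best[0]:
                best = (mm, idx, orientation)
                ties = 0
            elif mm == best[0]:
                ties += 1
    if best is None or best[0] / refs[best[1]].length > max_mismatch_frac:
        return None
    return refs[best[1]].gene, best[2], best[0], ties


# ---------------------------------------------------------------------------
# (iv) conversion filtering and CpG calling
# ---------------------------------------------------------------------------

def conversion_rate(seq: str, ref: AmpliconRef) -> tuple[float, int]:
    """Fraction of non-CpG reference cytosines read as T, and the number of
    informative positions. NaN when the amplicon has no non-CpG cytosine."""
    if ref.noncpg_c0.size == 0:
        return float("nan"), 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    sub = arr[ref.noncpg_c0]
    return float((sub == _T).mean()), int(ref.noncpg_c0.size)


def call_cpgs(seq: str, ref: AmpliconRef) -> str:
    """Per-CpG calls for an oriented (forward-strand) read: C -> '1'
    (methylated), T -> '0' (unmethylated), anything else -> '.' (missing)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    sub = arr[ref.cpg0]
    out = np.full(sub.size, ".", dtype="U1")
    out[sub == _C] = "1"
    out[sub == _T] = "0"
    return "".join(out)


def _calls_from_matrix(sub: np.ndarray) -> list[str]:
    out = np.full(sub.shape, ".", dtype="U1")
    out[sub == _C] = "1"
    out[sub == _T] = "0"
    return ["".join(row) for row in out]


def call_reads(
    reads: list[tuple[str, str]],
    panel: list[Amplicon],
    sample_sheet: pd.DataFrame,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    adaptor_len: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run demultiplexing, assignment, conversion filtering and calling.

    Returns the per-read call table (one row per barcode-assigned read) and
    a counter dict tracing every filtering step. ``retained`` marks reads
    that passed both amplicon assignment and the conversion-rate filter;
    reads with no informative non-CpG cytosine are retained with
    ``no_informative`` set. Reads are processed in batches grouped by
    length, so whole-cohort runs stay vectorized.
    """
    refs = build_references(panel)
    groups, n_unassigned_bc = demultiplex(reads, sample_sheet, adaptor_len)
    counts = {
        "reads_in": len(reads),
        "unassigned_barcode": n_unassigned_bc,
        "unassigned_amplicon": 0,
        "failed_conversion": 0,
        "no_informative": 0,
        "retained": 0,
        "assignment_ties": 0,
    }
    ids, libs, seqs = [], [], []
    for library_id, lib_reads in groups.items():
        for read_id, seq in lib_reads:
            ids.append(read_id)
            libs.append(library_id)
            seqs.append(seq)
    frames = []
    lengths = np.array([len(s) for s in seqs])
    for L in np.unique(lengths):
        idx = np.where(lengths == L)[0]
        cand = [(ri, r) for ri, r in enumerate(refs) if r.length == L]
        if not cand:
            counts["unassigned_amplicon"] += idx.size
            continue
        mat = np.frombuffer("".join(seqs[i] for i in idx).encode(),
                            dtype=np.uint8).reshape(idx.size, L)
        rc = _revcomp_rows(mat)
        # mismatch matrix: one column per (candidate, orientation), in panel
        # order with forward before reverse so argmin realizes the tie rule
        mm_cols, col_meta = [], []
        for ri, ref in cand:
            mm_cols.append(_mismatch_counts(mat, ref))
            col_meta.append((ri, "forward"))
            mm_cols.append(_mismatch_counts(rc, ref))
            col_meta.append((ri, "reverse"))
        mm = np.stack(mm_cols, axis=1)
        best_col = mm.argmin(axis=1)
        best_mm = mm[np.arange(idx.size), best_col]
        counts["assignment_ties"] += int(
            ((mm == best_mm[:, None]).sum(axis=1) - 1).sum()
        )
        assigned = best_mm / L <= max_mismatch_frac
        counts["unassigned_amplicon"] += int((~assigned).sum())
        for col, (ri, orientation) in enumerate(col_meta):
            sel = assigned & (best_col == col)
            if not sel.any():
                continue
            ref = refs[ri]
            oriented = (mat if orientation == "forward" else rc)[sel]
            n_inf = ref.noncpg_c0.size
            if n_inf:
                rate = (oriented[:, ref.noncpg_c0] == _T).mean(axis=1)
                retained = rate >= min_conversion
            else:
                rate = np.full(sel.sum(), np.nan)
                retained = np.ones(int(sel.sum()), dtype=bool)
            no_informative = n_inf == 0
            calls = _calls_from_matrix(oriented[:, ref.cpg0])
            which = idx[sel]
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": [ids[i] for i in which],
                        "library_id": [libs[i] for i in which],
                        "gene": ref.gene,
                        "orientation": orientation,
                        "mismatches": best_mm[sel],
                        "conversion_rate": rate,
                        "n_informative": n_inf,
                        "calls": [c if r else "" for c, r in zip(calls, retained)],
                        "retained": retained,
                        "no_informative": no_informative,
                    }
                )
            )
            counts["retained"] += int(retained.sum())
            if no_informative:
                counts["no_informative"] += int(sel.sum())
            else:
                counts["failed_conversion"] += int((~retained).sum())
    columns = [
        "read_id", "library_id", "gene", "orientation", "mismatches",
        "conversion_rate", "n_informative", "calls", "retained",
        "no_informative",
    ]
    if frames:
        table = pd.concat(frames, ignore_index=True)[columns]
    else:
        table = pd.DataFrame(columns=columns)
    return table, counts


# ---------------------------------------------------------------------------
# Aggregation and the coverage (read-depth) filter
# ---------------------------------------------------------------------------

def coverage_filter(
    p_hat: float,
    n: int,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[bool, float, float]:
    """Retention decision for one region-level measurement.

    The binomial SD of the mean methylation percentage is estimated as
    ``sqrt(p(1-p)/n)`` with n the retained read count. The measurement is
    retained when CV = SD/p < ``cv_threshold`` (strict) or
    SD <= ``sd_threshold`` (inclusive). Zero reads -> not retained; p of
    exactly 0 or 1 gives SD 0 and retention via the SD branch.
    """
    if n <= 0 or not np.isfinite(p_hat):
        return False, float("nan"), float("nan")
    sd = math.sqrt(p_hat * (1.0 - p_hat) / n)
    cv = sd / p_hat if p_hat > 0 else float("inf")
    return (cv < cv_threshold) or (sd <= sd_threshold), sd, cv


def minimal_retaining_n(
    p_hat: float,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> int:
    """Smallest read count at which a measurement with mean ``p_hat`` is
    retained by :func:`coverage_filter` (closed form plus a local scan to
    absorb floating-point boundary effects)."""
    bounds = []
    if p_hat > 0:
        bounds.append((1.0 - p_hat) / (p_hat * cv_threshold**2))  # CV branch
    bounds.append(p_hat * (1.0 - p_hat) / sd_threshold**2)        # SD branch
    n = max(1, int(math.floor(min(bounds))) - 2)
    while not coverage_filter(p_hat, n, cv_threshold, sd_threshold)[0]:
        n += 1
    return n


def aggregate(
    read_table: pd.DataFrame,
    panel: list[Amplicon],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate retained per-read calls into the methylation matrix.

    Returns ``(sites, regions)``: per (library, gene, site) methylated/total
    read counts and fraction; per (library, gene) the unweighted mean of the
    site fractions (over sites with >= 1 call), retained read count, and the
    coverage-filter decision with its SD/CV diagnostics.
    """
    n_cpg = {a.gene: a.n_cpg for a in panel}
    site_rows = []
    region_rows = []
    retained = read_table[read_table["retained"] & (read_table["calls"] != "")]
    for (library_id, gene), block in retained.groupby(["library_id", "gene"], sort=False):
        k = n_cpg[gene]
        calls = np.array([list(c) for c in block["calls"]], dtype="U1")
        meth = (calls == "1").sum(axis=0)
        total = meth + (calls == "0").sum(axis=0)
        frac = np.divide(meth, total, out=np.full(k, np.nan), where=total > 0)
        for j in range(k):
            site_rows.append(
                (library_id, gene, j + 1, int(meth[j]), int(total[j]),
                 float(frac[j]) if total[j] else float("nan"))
            )
        covered = total > 0
        region_mean = float(np.mean(frac[covered])) if covered.any() else float("nan")
        n_reads = int(len(block))
        keep, sd, cv = coverage_filter(region_mean, n_reads, cv_threshold, sd_threshold)
        region_rows.append(
            (library_id, gene, n_reads, region_mean, sd, cv, keep)
        )
    sites = pd.DataFrame(
        site_rows,
        columns=["library_id", "gene", "site", "methylated", "total", "fraction"],
    )
    regions = pd.DataFrame(
        region_rows,
        columns=["library_id", "gene", "n_reads", "region_mean", "sd_est",
                 "cv_est", "retained"],
    )
    return sites, regions
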