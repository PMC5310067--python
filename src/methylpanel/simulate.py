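"""Synthetic cohort and bisulfite-read simulator.

Generates sample metadata and amplicon bisulfite reads with the statistical
structure the downstream analysis assumes, so that every stage (calling,
filtering, group statistics, networks, classification) is testable without
patient data. The emulated design follows the study layout: 24 healthy
controls and 48 cystic-fibrosis patients in three lung-severity strata
(23 mild / 13 intermediary / 12 severe), two tissues (nasal epithelial
cells, NEC, and whole blood), a subset of patients lacking NEC material,
four patients with duplicated (technical replicate) measurements in both
tissues, and genotype-linked methylation at one locus via a 0/1/2 allele
dosage with an additive logit-scale effect.

The data-generating model, per subject s, tissue t, gene g and CpG site j:

    logit mu = logit(pi[g,t]) + site_offset[g,j] + group_offset[g,t,group(s)]
               + dosage[s,g] * slope[g] + sum_f loading_f * z[s,f]
    p ~ Beta(mu * c, (1 - mu) * c)          (c = concentration; c = inf -> p = mu)

Latent factors z ~ N(0,1) are shared across the genes/tissues they load on,
creating co-methylation modules and inter-tissue correlation; they may be
restricted to one stratum (e.g. disease-activated *trans* factors present
only in patients). Technical replicates share the same p; their disagreement
comes solely from read sampling, conversion failure and sequencing error.

Reads are emitted from the bisulfite-converted top strand: CpG cytosines
read C with probability p (methylation) and otherwise convert to T, subject
to a per-cytosine conversion-failure probability epsilon (an unmethylated C
that escapes conversion reads C); non-CpG cytosines read C with probability
epsilon, else T. Independent substitution errors are added and roughly half
of the reads are emitted as reverse complements (bidirectional sequencing
of the amplicon library).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Amplicon

CONTROL = "control"
CF_GROUPS = ("mild", "intermediary", "severe")
GROUPS = (CONTROL,) + CF_GROUPS
TISSUES = ("NEC", "blood")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit_f(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Library:
    """One sequencing library: a (subject, tissue, replicate) with a barcode."""

    library_id: str
    barcode: str
    subject_id: str
    group: str
    tissue: str
    replicate: int = 1


@dataclass
class CohortDesign:
    libraries: list[Library]
    dosages: pd.DataFrame  # index subject_id, one column per genotyped locus
    seed: int = 0

    def sample_sheet(self) -> pd.DataFrame:
        sheet = pd.DataFrame([vars(lib) for lib in self.libraries])
        return sheet.merge(
            self.dosages.rename(columns=lambda g: f"dosage_{g}"),
            left_on="subject_id",
            right_index=True,
            how="left",
        )

    @property
    def subjects(self) -> pd.DataFrame:
        sheet = pd.DataFrame([vars(lib) for lib in self.libraries])
        return sheet[["subject_id", "group"]].drop_duplicates().set_index("subject_id")


def _make_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Unique fixed-length sample barcodes (multiplex identifiers)."""
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def build_design(
    n_control: int = 24,
    n_mild: int = 23,
    n_intermediary: int = 13,
    n_severe: int = 12,
    n_nec_missing: int = 9,
    n_duplicated: int = 4,
    dosage_loci: dict[str, float] | None = None,
    seed: int = 0,
    barcode_length: int = 10,
) -> CohortDesign:
    """Build the cohort layout: subjects, tissues, replicates, genotypes.

    ``n_nec_missing`` patients contribute blood only (emulating NEC samples
    that yielded too little DNA); ``n_duplicated`` patients are measured
    twice in both tissues. ``dosage_loci`` maps locus (gene) name to the
    minor-allele frequency used to draw Hardy-Weinberg 0/1/2 dosages;
    defaults to ``{"GSTM3": 0.3}``.
    """
    if dosage_loci is None:
        dosage_loci = {"GSTM3": 0.3}
    rng = np.random.default_rng(seed)
    groups = (
        [CONTROL] * n_control
        + ["mild"] * n_mild
        + ["intermediary"] * n_intermediary
        + ["severe"] * n_severe
    )
    subjects = [
        (f"{'C' if g == CONTROL else 'CF'}{i:03d}", g) for i, g in enumerate(groups, 1)
    ]
    patient_ids = [s for s, g in subjects if g != CONTROL]
    nec_missing = set(rng.choice(patient_ids, size=n_nec_missing, replace=False))
    duplicated = set(
        rng.choice([s for s in patient_ids if s not in nec_missing],
                   size=n_duplicated, replace=False)
    )

    libraries: list[Library] = []
    for subject_id, group in subjects:
        for tissue in TISSUES:
            if tissue == "NEC" and subject_id in nec_missing:
                continue
            n_rep = 2 if subject_id in duplicated else 1
            for rep in range(1, n_rep + 1):
                libraries.append(
                    Library(
                        library_id=f"{subject_id}_{tissue}_r{rep}",
                        barcode="",
                        subject_id=subject_id,
                        group=group,
                        tissue=tissue,
                        replicate=rep,
                    )
                )
    barcodes = _make_barcodes(len(libraries), barcode_length, rng)
    libraries = [replace(lib, barcode=bc) for lib, bc in zip(libraries, barcodes)]

    dosages = pd.DataFrame(
        {
            locus: rng.binomial(2, maf, size=len(subjects))
            for locus, maf in dosage_loci.items()
        },
        index=pd.Index([s for s, _ in subjects], name="subject_id"),
    )
    return CohortDesign(libraries=libraries, dosages=dosages, seed=seed)


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoMethylationFactor:
    """A latent N(0,1) factor loading on several (gene, tissue) variables.

    ``strata`` restricts the factor to controls, to patients, or to both;
    a factor shared by both tissues of one gene induces inter-tissue
    correlation, one loading on several genes of one tissue induces an
    intra-tissue co-methylation module.
    """

    name: str
    genes: tuple[str, ...]
    tissues: tuple[str, ...]
    loading: float
    strata: tuple[str, ...] = ("control", "CF")


#: Baseline per-gene methylation by tissue, emulating the reported control
#: ranges: one gene near-complete (MUC5AC ~95% blood / ~83% NEC), one
#: intermediate (TLR5 ~38% / ~26%), the rest below 20%.
DEFAULT_BASELINES: dict[str, dict[str, float]] = {
    "MUC5AC": {"blood": 0.95, "NEC": 0.83},
    "TLR5": {"blood": 0.38, "NEC": 0.26},
    "ATF1": {"blood": 0.04, "NEC": 0.05},
    "CFTR": {"blood": 0.08, "NEC": 0.06},
    "DUOX2": {"blood": 0.05, "NEC": 0.07},
    "EDNRA": {"blood": 0.10, "NEC": 0.09},
    "ENaCg": {"blood": 0.06, "NEC": 0.05},
    "GSTM1": {"blood": 0.12, "NEC": 0.10},
    "GSTM3": {"blood": 0.15, "NEC": 0.13},
    "HMOX1": {"blood": 0.06, "NEC": 0.05},
    "IFRD1": {"blood": 0.05, "NEC": 0.04},
    "TGFB1": {"blood": 0.07, "NEC": 0.06},
    "TLR2": {"blood": 0.09, "NEC": 0.08},
    "YY1": {"blood": 0.03, "NEC": 0.04},
}


def _default_group_offsets() -> dict[tuple[str, str, str], float]:
    """Planted case/control and severity effects (logit scale), shaped like
    the reported findings: EDNRA hypomethylated in patient blood with a
    severity trend, HMOX1 down in blood and up (non-monotonically) in NEC,
    GSTM3 severity trend in NEC."""
    off: dict[tuple[str, str, str], float] = {}
    for grp, d in zip(CF_GROUPS, (-0.4, -0.6, -0.8)):
        off[("EDNRA", "blood", grp)] = d
    for grp, d in zip(CF_GROUPS, (-0.5, -0.6, -0.7)):
        off[("HMOX1", "blood", grp)] = d
    for grp, d in zip(CF_GROUPS, (0.7, 0.2, 0.8)):  # U-shaped in severity
        off[("HMOX1", "NEC", grp)] = d
    for grp, d in zip(CF_GROUPS, (0.0, -0.4, -0.8)):
        off[("GSTM3", "NEC", grp)] = d
    return off


def _default_factors() -> tuple[CoMethylationFactor, ...]:
    return (
        CoMethylationFactor(
            "nec_cf_module", ("TLR5", "MUC5AC", "CFTR", "HMOX1"), ("NEC",),
            loading=0.6, strata=("CF",),
        ),
        CoMethylationFactor(
            "gstm3_intertissue", ("GSTM3",), ("NEC", "blood"),
            loading=0.8, strata=("control", "CF"),
        ),
    )


@dataclass
class TruthModel:
    """All parameters of the data-generating model (see module docstring)."""

    baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(t) for g, t in DEFAULT_BASELINES.items()}
    )
    #: (gene, 1-based site) -> logit offset; one CpG can sit above its region
    #: (like the reported ~30% site in an otherwise <10% island).
    site_offsets: dict[tuple[str, int], float] = field(
        default_factory=lambda: {("HMOX1", 2): 2.2}
    )
    group_offsets: dict[tuple[str, str, str], float] = field(
        default_factory=_default_group_offsets
    )
    dosage_slopes: dict[str, float] = field(default_factory=lambda: {"GSTM3": -0.5})
    factors: tuple[CoMethylationFactor, ...] = field(default_factory=_default_factors)
    concentration: float = 40.0
    conversion_failure: float = 0.01
    sequencing_error: float = 0.002
    depth_range: tuple[int, int] = (9, 2704)

    def mean_logit(self, gene: str, tissue: str, group: str, site: int,
                   dosage: float = 0.0) -> float:
        mu = logit_f(self.baselines[gene][tissue])
        mu += self.site_offsets.get((gene, site), 0.0)
        mu += self.group_offsets.get((gene, tissue, group), 0.0)
        mu += dosage * self.dosage_slopes.get(gene, 0.0)
        return float(mu)


def null_truth(**overrides) -> TruthModel:
    """A truth model with no planted effects (for calibration experiments)."""
    base = dict(site_offsets={}, group_offsets={}, dosage_slopes={}, factors=())
    base.update(overrides)
    return TruthModel(**base)


# ---------------------------------------------------------------------------
# Per-sample methylation probabilities
# ---------------------------------------------------------------------------

def simulate_sample_methylation(
    design: CohortDesign,
    truth: TruthModel,
    panel: list[Amplicon],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the latent per-CpG methylation probability p for every library.

    Returns a long table (library_id, subject_id, group, tissue, gene, site,
    p). Technical replicates of one (subject, tissue) share identical p:
    they re-measure the same biological material.
    """
    subj = design.subjects
    z = {
        f.name: pd.Series(rng.standard_normal(len(subj)), index=subj.index)
        for f in truth.factors
    }
    p_cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    rows = []
    for lib in design.libraries:
        key = (lib.subject_id, lib.tissue)
        if key not in p_cache:
            group = lib.group
            stratum = "control" if group == CONTROL else "CF"
            p_cache[key] = {}
            for amp in panel:
                dosage = (
                    float(design.dosages.loc[lib.subject_id, amp.gene])
                    if amp.gene in design.dosages.columns
                    else 0.0
                )
                mu = np.array(
                    [
                        truth.mean_logit(amp.gene, lib.tissue, group, j, dosage)
                        for j in range(1, amp.n_cpg + 1)
                    ]
                )
                for f in truth.factors:
                    if (
                        amp.gene in f.genes
                        and lib.tissue in f.tissues
                        and stratum in f.strata
                    ):
                        mu = mu + f.loading * z[f.name][lib.subject_id]
                mean_p = logistic(mu)
                if math.isinf(truth.concentration):
                    p = mean_p
                else:
                    c = truth.concentration
                    p = rng.beta(mean_p * c, (1.0 - mean_p) * c)
                p_cache[key][amp.gene] = p
        for amp in panel:
            for j, p_site in enumerate(p_cache[key][amp.gene], start=1):
                rows.append(
                    (lib.library_id, lib.subject_id, lib.group, lib.tissue,
                     amp.gene, j, float(p_site))
                )
    return pd.DataFrame(
        rows,
        columns=["library_id", "subject_id", "group", "tissue", "gene", "site", "p"],
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _draw_depth(truth: TruthModel, rng: np.random.Generator) -> int:
    lo, hi = truth.depth_range
    if lo == hi:
        return int(lo)
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def simulate_reads(
    sample_p: pd.DataFrame,
    panel: list[Amplicon],
    design: CohortDesign,
    truth: TruthModel,
    rng: np.random.Generator,
    depth: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit barcoded bisulfite reads for every (library, gene).

    Returns ``(reads, read_truth)`` where ``reads`` is a list of
    (read_id, sequence) with the library barcode prepended, and
    ``read_truth`` records, per read, the originating library, gene,
    orientation and the realized conversion rate observable in the emitted
    bases (fraction of non-CpG reference-C positions that read T). ``depth``
    fixes the per-amplicon read count; by default it is drawn log-uniformly
    from ``truth.depth_range`` independently per (library, gene).
    """
    amp_by_gene = {a.gene: a for a in panel}
    bc_by_lib = {lib.library_id: lib.barcode for lib in design.libraries}
    base_idx = {b: i for i, b in enumerate("ACGT")}

    reads: list[tuple[str, str]] = []
    truth_rows = []
    grouped = sample_p.groupby(["library_id", "gene"], sort=False)
    for (library_id, gene), block in grouped:
        amp = amp_by_gene[gene]
        p = block.sort_values("site")["p"].to_numpy()
        n = _draw_depth(truth, rng) if depth is None else depth
        if n == 0:
            continue
        L = len(amp.sequence)
        ref = np.frombuffer(amp.sequence.encode(), dtype=np.uint8)
        cpg0 = np.array([q - 1 for q in amp.cpg_positions], dtype=int)
        is_c = ref == ord("C")
        noncpg_c = np.where(is_c & ~np.isin(np.arange(L), cpg0))[0]

        mat = np.tile(ref, (n, 1))
        # CpG cytosines: C if methylated, else C with prob eps (conversion
        # failure) else T
        meth = rng.random((n, cpg0.size)) < p[None, :]
        escaped = rng.random((n, cpg0.size)) < truth.conversion_failure
        cpg_base = np.where(meth | escaped, ord("C"), ord("T"))
        mat[:, cpg0] = cpg_base
        # non-CpG cytosines: converted to T unless conversion fails
        fail = rng.random((n, noncpg_c.size)) < truth.conversion_failure
        mat[:, noncpg_c] = np.where(fail, ord("C"), ord("T"))
        # independent substitution errors
        err = rng.random((n, L)) < truth.sequencing_error
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            cur = np.array([base_idx[chr(b)] for b in mat[err]])
            mat[err] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[(cur + shift) % 4]

        conv = (
            (mat[:, noncpg_c] == ord("T")).mean(axis=1)
            if noncpg_c.size
            else np.full(n, np.nan)
        )
        rev = rng.random(n) < 0.5
        barcode = bc_by_lib[library_id]
        for i in range(n):
            seq = mat[i].tobytes().decode()
            if rev[i]:
                seq = seq.translate(_COMPLEMENT)[::-1]
            read_id = f"{library_id}|{gene}|{i:05d}"
            reads.append((read_id, barcode + seq))
            truth_rows.append(
                (read_id, library_id, gene,
                 "reverse" if rev[i] else "forward", float(conv[i]))
            )
    read_truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "library_id", "gene", "orientation", "conversion_rate"],
    )
    return reads, read_truth


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(fh)]


def write_sample_sheet(design: CohortDesign, path: str | Path) -> None:
    design.sample_sheet().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
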