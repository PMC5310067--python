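"""Amplicon panel model for targeted bisulfite sequencing.

A panel is a small set of PCR amplicons (here 14 regions of 133-260 bp over
*CFTR* and 13 cystic-fibrosis lung-disease modifier genes) in which DNA
methylation is read out per CpG dinucleotide after bisulfite conversion.
This module models the regions, indexes their CpG sites, builds in-silico
bisulfite-converted references used for read assignment and calling, and
validates a panel against its declared metadata (CpG count, amplicon size).

Conventions
-----------
* Genomic coordinates are 1-based inclusive (GRCh38), so length is
  ``end - start + 1``.
* CpG sites are numbered 1-based in 5'->3' order along the amplicon
  sequence; ``cpg_positions`` are the 1-based offsets of the C of each CG.
* Bisulfite-converted reference patterns use the IUPAC code ``Y`` (C or T)
  at CpG cytosines, whose readout carries the methylation signal; every
  other cytosine is deaminated and reads as T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_RE = re.compile(r"^[ACGT]+$")

GENOME_ASSEMBLY = "GRCh38"


class PanelError(ValueError):
    """Invalid panel definition (bad region, alphabet, or metadata)."""


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    assembly: str = GENOME_ASSEMBLY

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise PanelError("genomic coordinates are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def region_length(region: GenomicRegion) -> int:
    """Length in bp of a 1-based inclusive region (``end - start + 1``)."""
    return region.length


def find_cpgs(sequence: str) -> list[int]:
    """1-based offsets of every CG dinucleotide start in ``sequence``.

    Raises
    ------
    PanelError
        If the sequence contains characters outside {A, C, G, T}.
    """
    if sequence and not _DNA_RE.match(sequence):
        bad = sorted(set(sequence) - set("ACGT"))
        raise PanelError(f"sequence contains non-ACGT characters: {bad}")
    return [m.start() + 1 for m in re.finditer("(?=CG)", sequence)]


@dataclass(frozen=True)
class Amplicon:
    """One target region of the panel with its sequence and CpG index."""

    gene: str
    region: GenomicRegion
    sequence: str = ""
    declared_n_cpg: int | None = None
    declared_size: int | None = None
    cpg_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sequence:
            found = tuple(find_cpgs(self.sequence))
            if self.cpg_positions and tuple(self.cpg_positions) != found:
                raise PanelError(
                    f"{self.gene}: supplied cpg_positions disagree with sequence"
                )
            object.__setattr__(self, "cpg_positions", found)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return len(self.sequence) if self.sequence else self.region.length


@dataclass(frozen=True)
class BisulfiteReference:
    """In-silico bisulfite-converted reference patterns for one amplicon.

    ``top_converted`` is the amplicon sequence with every non-CpG cytosine
    deaminated to T and each CpG cytosine left ambiguous (``Y`` = C or T);
    ``bottom_converted`` is the same construction applied to the reverse
    complement. The ambiguous positions of the top pattern are exactly the
    amplicon's CpG positions.
    """

    amplicon: Amplicon
    top_converted: str
    bottom_converted: str

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, b in enumerate(self.top_converted) if b == "Y")


def _convert_strand(sequence: str) -> str:
    cpg = set(p - 1 for p in find_cpgs(sequence))
    out = []
    for i, base in enumerate(sequence):
        if base != "C":
            out.append(base)
        elif i in cpg:
            out.append("Y")
        else:
            out.append("T")
    return "".join(out)


def bisulfite_convert(amplicon: Amplicon) -> BisulfiteReference:
    """Build the top- and bottom-strand bisulfite reference for an amplicon.

    Idempotent in the sense that a sequence without cytosines (i.e. already
    fully converted) is returned unchanged.
    """
    if not amplicon.sequence:
        raise PanelError(f"{amplicon.gene}: no sequence supplied")
    return BisulfiteReference(
        amplicon=amplicon,
        top_converted=_convert_strand(amplicon.sequence),
        bottom_converted=_convert_strand(reverse_complement(amplicon.sequence)),
    )


# ---------------------------------------------------------------------------
# The packaged 14-gene cystic-fibrosis panel
# ---------------------------------------------------------------------------

#: gene, chrom, start, end, declared CpG count, declared amplicon size (bp).
#: The EDNRA end coordinate is the corrected full value (the truncated form
#: misses its leading digit; only 147,481,216 is consistent with the declared
#: 260 bp size) — validate_panel documents this correction.
PANEL_DEFINITION: list[tuple[str, str, int, int, int, int]] = [
    ("ATF1", "chr12", 50_764_850, 50_765_098, 12, 249),
    ("CFTR", "chr7", 117_479_627, 117_479_759, 10, 133),
    ("DUOX2", "chr15", 45_114_541, 45_114_722, 11, 182),
    ("EDNRA", "chr4", 147_480_957, 147_481_216, 21, 260),
    ("ENaCg", "chr16", 23_182_420, 23_182_665, 23, 246),
    ("GSTM1", "chr1", 109_687_687, 109_687_897, 13, 211),
    ("GSTM3", "chr1", 109_740_573, 109_740_793, 9, 221),
    ("HMOX1", "chr22", 35_381_269, 35_381_436, 5, 168),
    ("IFRD1", "chr7", 112_450_883, 112_451_040, 12, 158),
    ("MUC5AC", "chr11", 1_194_622, 1_194_807, 13, 186),
    ("TGFB1", "chr19", 41_353_542, 41_353_740, 19, 199),
    ("TLR2", "chr4", 153_684_576, 153_684_704, 12, 129),
    ("TLR5", "chr1", 223_142_813, 223_142_967, 8, 155),
    ("YY1", "chr14", 100_240_497, 100_240_751, 26, 255),
]

PANEL_GENES = [row[0] for row in PANEL_DEFINITION]


def _synthetic_sequence(length: int, n_cpg: int, rng: np.random.Generator) -> str:
    """Random DNA of ``length`` bp containing exactly ``n_cpg`` CG dinucleotides.

    Synthetic stand-in for the genomic sequence of a panel amplicon: the
    true reference base sequence is not bundled, so packaged panels carry a
    sequence matching the declared length and CpG count (which is all the
    calling machinery depends on). A backbone free of CG is drawn first,
    then CG pairs are planted at non-adjacent offsets.
    """
    if n_cpg > (length // 2):
        raise PanelError("cannot place that many non-overlapping CpGs")
    bases = "ACGT"
    seq = []
    for _ in range(length):
        b = bases[rng.integers(4)]
        while seq and seq[-1] == "C" and b == "G":
            b = bases[rng.integers(4)]
        seq.append(b)
    # choose CG start offsets (0-based) at least 2 apart, away from the ends
    while True:
        starts = np.sort(rng.choice(length - 1, size=n_cpg, replace=False))
        if n_cpg < 2 or np.all(np.diff(starts) >= 2):
            break
    for s in starts:
        seq[s] = "C"
        seq[s + 1] = "G"
        # planting C at s can create an upstream CG only via seq[s-1]=='C'?
        # no: CG needs C then G; seq[s]=='C' cannot terminate a CG. Planting
        # G at s+1 creates a new CG only if seq[s]=='C', which is intended.
    out = "".join(seq)
    assert len(find_cpgs(out)) == n_cpg
    return out


def builtin_panel(seed: int = 20_170_214) -> list[Amplicon]:
    """The packaged 14-gene panel with synthetic amplicon sequences.

    Coordinates, CpG counts and sizes follow the published panel metadata;
    the base sequences are deterministic synthetic stand-ins with exactly
    the declared length and CpG count (see :func:`_synthetic_sequence`).
    """
    rng = np.random.default_rng(seed)
    amplicons = []
    for gene, chrom, start, end, n_cpg, size in PANEL_DEFINITION:
        region = GenomicRegion(chrom, start, end)
        seq = _synthetic_sequence(region.length, n_cpg, rng)
        amplicons.append(
            Amplicon(
                gene=gene,
                region=region,
                sequence=seq,
                declared_n_cpg=n_cpg,
                declared_size=size,
            )
        )
    return amplicons


def validate_panel(panel: list[Amplicon]) -> pd.DataFrame:
    """Check every amplicon's computed length and CpG count against its
    declared metadata.

    Returns a tidy report with one row per (gene, field) discrepancy and
    zero rows for a fully consistent panel. Region length is checked against
    ``declared_size``; if a sequence is present, its length and CpG count are
    checked against the region length and ``declared_n_cpg``.
    """
    if not panel:
        raise PanelError("empty panel")
    rows = []

    def flag(gene: str, fld: str, declared, computed) -> None:
        if declared is not None and declared != computed:
            rows.append(
                {"gene": gene, "field": fld, "declared": declared, "computed": computed}
            )

    for amp in panel:
        flag(amp.gene, "size", amp.declared_size, amp.region.length)
        if amp.sequence:
            flag(amp.gene, "sequence_length", amp.region.length, len(amp.sequence))
            flag(amp.gene, "n_cpg", amp.declared_n_cpg, amp.n_cpg)
    return pd.DataFrame(rows, columns=["gene", "field", "declared", "computed"])


# ---------------------------------------------------------------------------
# Panel IO: FASTA (sequences) + TSV sidecar (metadata)
# ---------------------------------------------------------------------------

def write_panel(panel: list[Amplicon], fasta_path: str | Path, tsv_path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(a.sequence),
            id=a.gene,
            description=f"{a.region.chrom}:{a.region.start}-{a.region.end}",
        )
        for a in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "gene": a.gene,
                "chrom": a.region.chrom,
                "start": a.region.start,
                "end": a.region.end,
                "declared_n_cpg": a.declared_n_cpg,
                "declared_size": a.declared_size,
            }
            for a in panel
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def load_panel(fasta_path: str | Path, tsv_path: str | Path) -> list[Amplicon]:
    meta = pd.read_csv(tsv_path, sep="\t").set_index("gene")
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        panel.append(
            Amplicon(
                gene=rec.id,
                region=GenomicRegion(str(row["chrom"]), int(row["start"]), int(row["end"])),
                sequence=str(rec.seq).upper(),
                declared_n_cpg=int(row["declared_n_cpg"]),
                declared_size=int(row["declared_size"]),
            )
        )
    if not panel:
        raise PanelError(f"no records in {fasta_path}")
    return panel
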