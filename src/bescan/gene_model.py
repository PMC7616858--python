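"""Gene model loading, validation and coordinate arithmetic.

A :class:`GeneModel` bundles a reference contig with the exon/CDS structure
of a single protein-coding gene and the protein it encodes.  All internal
coordinates are 0-based half-open on the contig; user-facing I/O (GFF3)
uses the standard 1-based inclusive convention.  Minus-strand genes are
fully supported: "coding strand" operations work on the reverse complement.

The model deliberately assumes a wild-type reference as the editing
baseline — no sample-specific variants are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gffutils
from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "GeneModelError",
    "translate",
    "reverse_complement",
    "extract_cds",
    "splice_sites",
    "load_gene_model",
    "write_gene_model",
]

_VALID_BASES = frozenset("ACGT")


class GeneModelError(ValueError):
    """Raised when a gene model violates a structural invariant."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds_seq: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    The trailing stop, if present, is represented explicitly as ``*``.
    Internal stops are translated as ``*`` too; structural validation is
    the caller's job (see :meth:`GeneModel.validate`).

    Raises
    ------
    GeneModelError
        If the length is not divisible by 3 or the sequence contains a
        base outside A/C/G/T.
    """
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise GeneModelError(
            f"CDS length {len(seq)} not divisible by 3"
        )
    bad = set(seq) - _VALID_BASES
    if bad:
        raise GeneModelError(f"ambiguous or invalid base(s) in CDS: {sorted(bad)}")
    return str(Seq(seq).translate())


@dataclass
class GeneModel:
    """A single gene on a single contig.

    Parameters
    ----------
    exons, cds
        Ordered (by contig position) lists of 0-based half-open intervals.
        Every CDS interval must be contained in an exon.
    promoter
        Optional interval upstream of the gene (contig orientation).
    strand
        ``+`` or ``-``; CDS extraction reverse-complements for ``-``.
    """

    gene_id: str
    contig_id: str
    contig_seq: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    promoter: tuple[int, int] | None = None
    protein: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.contig_seq = self.contig_seq.upper()
        self.exons = [tuple(e) for e in sorted(self.exons)]
        self.cds = [tuple(c) for c in sorted(self.cds)]
        if not self.protein:
            self.protein = translate(extract_cds(self)).rstrip("*")

    # -- structure ---------------------------------------------------------

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in contig order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def footprint(self) -> tuple[int, int]:
        """Gene span on the contig (exons plus promoter if present)."""
        starts = [e[0] for e in self.exons]
        ends = [e[1] for e in self.exons]
        if self.promoter is not None:
            starts.append(self.promoter[0])
            ends.append(self.promoter[1])
        return min(starts), max(ends)

    def cds_positions(self) -> list[int]:
        """Contig positions of CDS bases in coding (5'->3' mRNA) order."""
        pos = [p for s, e in self.cds for p in range(s, e)]
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_index(self, contig_pos: int) -> int | None:
        """Index of a contig position within the coding-strand CDS, or None."""
        # linear scan over intervals; genes here are small
        offset = 0
        total = sum(e - s for s, e in self.cds)
        for s, e in self.cds:
            if s <= contig_pos < e:
                idx = offset + (contig_pos - s)
                if self.strand == "-":
                    return total - 1 - idx
                return idx
            offset += e - s
        return None

    def in_intron(self, contig_pos: int) -> bool:
        return any(s <= contig_pos < e for s, e in self.introns)

    def in_promoter(self, contig_pos: int) -> bool:
        if self.promoter is None:
            return False
        s, e = self.promoter
        return s <= contig_pos < e

    # -- validation --------------------------------------------------------

    def validate(self, strict_splice: bool = True) -> None:
        """Check all structural invariants; raise :class:`GeneModelError`.

        Non-canonical splice dinucleotides raise when ``strict_splice``
        (synthetic fixtures guarantee GT/AG) and warn otherwise, matching
        how real annotations behave.
        """
        if self.strand not in "+-":
            raise GeneModelError(f"strand must be + or -, got {self.strand!r}")
        n = len(self.contig_seq)
        for s, e in self.exons + self.cds:
            if not (0 <= s < e <= n):
                raise GeneModelError(f"interval [{s},{e}) outside contig of length {n}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise GeneModelError(f"exons [{s1},{e1}) and [{s2},{e2}) overlap")
        for c in self.cds:
            if not any(es <= c[0] and c[1] <= ee for es, ee in self.exons):
                raise GeneModelError(f"CDS interval [{c[0]},{c[1]}) not contained in an exon")
        cds_len = sum(e - s for s, e in self.cds)
        if cds_len % 3 != 0:
            raise GeneModelError(
                f"CDS length {cds_len} not divisible by 3 (intervals {self.cds})"
            )
        prot = translate(extract_cds(self))
        internal = prot[:-1].find("*")
        if internal != -1:
            raise GeneModelError(f"internal stop codon at codon index {internal}")
        if not prot.endswith("*"):
            raise GeneModelError("CDS does not end at a stop codon")
        for i, (s, e) in enumerate(self.introns):
            intron = self.contig_seq[s:e]
            if self.strand == "-":
                intron = reverse_complement(intron)
            if not (intron.startswith("GT") and intron.endswith("AG")):
                msg = (
                    f"intron {i} is non-canonical "
                    f"({intron[:2]}..{intron[-2:]}, expected GT..AG)"
                )
                if strict_splice:
                    raise GeneModelError(msg)
                warnings.warn(msg, stacklevel=2)


def extract_cds(model: GeneModel) -> str:
    """Coding-strand CDS sequence (reverse-complemented for minus genes)."""
    seq = "".join(model.contig_seq[s:e] for s, e in model.cds)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def splice_sites(model: GeneModel) -> list[tuple[int, str, str]]:
    """Canonical 2-nt splice-core positions, coding-strand oriented.

    Returns ``(contig_position, kind, base)`` tuples where *kind* is
    ``donor`` (the GT at the coding-strand 5' end of each intron) or
    ``acceptor`` (the AG at its 3' end), and *base* is the coding-strand
    base.  Empty for single-exon genes.
    """
    sites: list[tuple[int, str, str]] = []
    for s, e in model.introns:
        if model.strand == "+":
            donor_pos, acceptor_pos = (s, s + 1), (e - 2, e - 1)
        else:
            donor_pos, acceptor_pos = (e - 1, e - 2), (s + 1, s)
        for p in donor_pos:
            base = model.contig_seq[p]
            if model.strand == "-":
                base = reverse_complement(base)
            sites.append((p, "donor", base))
        for p in acceptor_pos:
            base = model.contig_seq[p]
            if model.strand == "-":
                base = reverse_complement(base)
            sites.append((p, "acceptor", base))
    return sites


def load_gene_model(
    fasta_path: str,
    gff_path: str,
    gene_id: str,
    strict_splice: bool = False,
) -> GeneModel:
    """Load and validate a gene model from FASTA + GFF3.

    GFF3 1-based inclusive coordinates are converted to the internal
    0-based half-open convention; the protein sequence is derived.
    """
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise GeneModelError(f"gene {gene_id!r} not found in {gff_path}") from exc

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    if gene.seqid not in contigs:
        raise GeneModelError(
            f"contig {gene.seqid!r} referenced by {gene_id!r} missing from {fasta_path}"
        )

    def intervals(featuretype: str) -> list[tuple[int, int]]:
        return sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype=featuretype)
        )

    exons = intervals("exon")
    cds = intervals("CDS")
    if not exons or not cds:
        raise GeneModelError(f"gene {gene_id!r} lacks exon and/or CDS features")
    promoters = intervals("promoter")

    model = GeneModel(
        gene_id=gene_id,
        contig_id=gene.seqid,
        contig_seq=contigs[gene.seqid],
        strand=gene.strand,
        exons=exons,
        cds=cds,
        promoter=promoters[0] if promoters else None,
    )
    model.validate(strict_splice=strict_splice)
    return model


def write_gene_model(model: GeneModel, fasta_path: str, gff_path: str) -> None:
    """Write the contig as FASTA and the gene structure as GFF3."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.contig_id}\n")
        seq = model.contig_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    def line(ftype: str, s: int, e: int, attrs: str) -> str:
        return "\t".join(
            [
                model.contig_id,
                "bescan",
                ftype,
                str(s + 1),
                str(e),
                ".",
                model.strand,
                ".",
                attrs,
            ]
        )

    lo, hi = model.footprint
    rows = [line("gene", lo, hi, f"ID={model.gene_id}")]
    for i, (s, e) in enumerate(model.exons, 1):
        rows.append(
            line("exon", s, e, f"ID={model.gene_id}.exon{i};Parent={model.gene_id}")
        )
    for i, (s, e) in enumerate(model.cds, 1):
        rows.append(
            line("CDS", s, e, f"ID={model.gene_id}.cds{i};Parent={model.gene_id}")
        )
    if model.promoter is not None:
        s, e = model.promoter
        rows.append(
            line("promoter", s, e, f"ID={model.gene_id}.promoter;Parent={model.gene_id}")
        )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(rows) + "\n")
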