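"""Codon-aware pairwise and quartet alignment.

Coding sequences are aligned at the protein level (global Needleman-Wunsch
with affine gaps) and the protein alignment is back-translated onto the
source codons, so every gap run in the DNA alignment has length divisible by
three and no frameshift can arise.  Quartet alignments for the branch models
are built by star alignment to a reference species (human), merging the gap
patterns of the pairwise alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io import CodingSequence, ValidationError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


class NoOrfError(ValueError):
    """No ATG-initiated, stop-terminated open reading frame found."""


class ConsistencyError(ValueError):
    """Protein rows and coding sequences disagree."""


@dataclass
class ProteinAlignment:
    """Global pairwise protein alignment; rows are equal-length gapped strings."""

    gene_id: str
    species_a: str
    species_b: str
    rows: tuple[str, str]
    score: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b):
            raise ValidationError("alignment rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(a, b)):
            raise ValidationError("alignment contains a gap/gap column")

    def __len__(self) -> int:
        return len(self.rows[0])


@dataclass
class CodonAlignment:
    """Back-translated DNA alignment; gap runs are whole codons."""

    gene_id: str
    species_a: str
    species_b: str
    rows: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b) or len(a) % 3 != 0:
            raise ValidationError("codon alignment rows must be equal length, multiple of 3")

    def __len__(self) -> int:
        return len(self.rows[0])

    def ungapped(self) -> tuple[str, str]:
        return tuple(r.replace("-", "") for r in self.rows)


def longest_orf(dna: str, gene_id: str = "", species: str = "") -> CodingSequence:
    """Longest ATG-initiated, stop-terminated ORF over the 3 forward frames.

    The stop codon is trimmed; ties are broken by the leftmost start.
    Raises NoOrfError when no complete ORF exists.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise NoOrfError("sequence shorter than one codon")
    best: tuple[int, int] | None = None  # (start, length)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(dna) - 2, 3):
            codon = dna[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                length = pos - start
                if best is None or length > best[1] or (length == best[1] and start < best[0]):
                    best = (start, length)
                start = None  # scan continues; unterminated ORFs are not accepted
    if best is None or best[1] == 0:
        raise NoOrfError("no ATG-initiated, stop-terminated ORF found")
    start, length = best
    return CodingSequence(gene_id, species, dna[start : start + length], frame_validated=True)


def translate(cds: CodingSequence | str) -> str:
    """Translate a frame-validated CDS; codons containing N become 'X'."""
    dna = cds.dna if isinstance(cds, CodingSequence) else cds
    if len(dna) % 3 != 0:
        raise ValidationError("CDS length is not a multiple of 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOPS:
            raise ValidationError(f"internal stop codon {codon} at nt {i}")
        else:
            out.append(_TABLE.forward_table[codon])
    return "".join(out)


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except (FileNotFoundError, ValueError) as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins(
    p1: str,
    p2: str,
    gene_id: str = "",
    species_a: str = "",
    species_b: str = "",
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ProteinAlignment:
    """Optimal global alignment of two protein sequences, affine gap costs.

    Deterministic: among co-optimal alignments the first in the aligner's
    fixed enumeration order is returned.
    """
    if not p1 or not p2:
        raise ValidationError("cannot align empty protein sequence")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    aln = next(iter(aligner.align(p1, p2)))
    return ProteinAlignment(gene_id, species_a, species_b, (str(aln[0]), str(aln[1])), float(aln.score))


def backtranslate(
    pa: ProteinAlignment, cds_a: CodingSequence, cds_b: CodingSequence
) -> CodonAlignment:
    """Replace each aligned residue by its source codon, each gap by '---'."""
    rows_dna = []
    for row, cds in ((pa.rows[0], cds_a), (pa.rows[1], cds_b)):
        protein = translate(cds)
        if row.replace("-", "") != protein:
            raise ConsistencyError(
                f"{pa.gene_id}: protein row does not match translation of "
                f"{cds.gene_id}|{cds.species}"
            )
        out, k = [], 0
        for aa in row:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds.dna[3 * k : 3 * k + 3])
                k += 1
        rows_dna.append("".join(out))
    return CodonAlignment(pa.gene_id, pa.species_a, pa.species_b, tuple(rows_dna))


def align_codon_pair(
    cds_a: CodingSequence, cds_b: CodingSequence, **aligner_kwargs
) -> tuple[ProteinAlignment, CodonAlignment]:
    """Protein-align two CDSs and back-translate: the transAlign procedure."""
    pa = align_proteins(
        translate(cds_a), translate(cds_b),
        gene_id=cds_a.gene_id, species_a=cds_a.species, species_b=cds_b.species,
        **aligner_kwargs,
    )
    return pa, backtranslate(pa, cds_a, cds_b)


# ---------------------------------------------------------------------------
# Quartet star alignment


@dataclass
class MultiCodonAlignment:
    """Codon alignment of several species built by star alignment."""

    gene_id: str
    species: tuple[str, ...]
    rows: tuple[str, ...]

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]


def star_align_codons(
    sequences: dict[str, CodingSequence],
    reference: str = "human",
    **aligner_kwargs,
) -> MultiCodonAlignment:
    """Multi-species codon alignment via star alignment to a reference.

    Each non-reference species is protein-aligned to the reference pairwise;
    insertions relative to the reference are merged with the usual
    "once a gap, always a gap" rule, then all rows are back-translated.
    """
    if reference not in sequences:
        raise ValidationError(f"reference species {reference!r} missing from input")
    ref_cds = sequences[reference]
    ref_prot = translate(ref_cds)
    others = [sp for sp in sequences if sp != reference]

    pairwise: dict[str, ProteinAlignment] = {
        sp: align_proteins(
            ref_prot, translate(sequences[sp]),
            gene_id=ref_cds.gene_id, species_a=reference, species_b=sp,
            **aligner_kwargs,
        )
        for sp in others
    }

    # insertion length needed after each reference residue position
    # slot r = before reference residue r (r in 0..len(ref_prot))
    ins = [0] * (len(ref_prot) + 1)
    for pa in pairwise.values():
        r, run = 0, 0
        for a in pa.rows[0]:
            if a == "-":
                run += 1
            else:
                ins[r] = max(ins[r], run)
                run, r = 0, r + 1
        ins[r] = max(ins[r], run)

    def expand(pa: ProteinAlignment | None) -> tuple[str, str]:
        """Re-space one pairwise alignment onto the merged column grid."""
        if pa is None:  # the reference itself
            ref_row = []
            for r, aa in enumerate(ref_prot):
                ref_row.append("-" * ins[r] + aa)
            ref_row.append("-" * ins[len(ref_prot)])
            merged = "".join(ref_row)
            return merged, merged
        out_ref, out_other = [], []
        r, run_start = 0, 0
        row_ref, row_other = pa.rows
        i = 0
        while i <= len(row_ref):
            # collect the insertion run (gaps in reference row) before residue r
            run = []
            while i < len(row_ref) and row_ref[i] == "-":
                run.append(row_other[i])
                i += 1
            pad = ins[r] - len(run)
            out_ref.append("-" * ins[r])
            out_other.append("".join(run) + "-" * pad)
            if i < len(row_ref):
                out_ref.append(row_ref[i])
                out_other.append(row_other[i])
                r += 1
                i += 1
            else:
                break
        return "".join(out_ref), "".join(out_other)

    merged_ref, _ = expand(None)
    species_order = (reference, *others)
    prot_rows = {reference: merged_ref}
    for sp in others:
        exp_ref, exp_other = expand(pairwise[sp])
        if exp_ref.replace("-", "") != ref_prot:
            raise ConsistencyError("star merge corrupted the reference row")
        prot_rows[sp] = exp_other

    width = len(merged_ref)
    if any(len(prot_rows[sp]) != width for sp in species_order):
        raise ConsistencyError("star merge produced ragged rows")

    dna_rows = []
    for sp in species_order:
        cds = sequences[sp]
        out, k = [], 0
        for aa in prot_rows[sp]:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds.dna[3 * k : 3 * k + 3])
                k += 1
        if k * 3 != len(cds.dna):
            raise ConsistencyError(f"{sp}: residues consumed do not cover the CDS")
        dna_rows.append("".join(out))
    return MultiCodonAlignment(ref_cds.gene_id, species_order, tuple(dna_rows))


def write_alignment_fasta(aln, path, separator: str = "|") -> None:
    """Write a pairwise or multi alignment as gapped FASTA."""
    if isinstance(aln, (ProteinAlignment, CodonAlignment)):
        names = (aln.species_a, aln.species_b)
    else:
        names = aln.species
    with open(path, "w") as fh:
        for name, row in zip(names, aln.rows):
            fh.write(f">{aln.gene_id}{separator}{name}\n{row}\n")
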