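"""ORF integrity and activity classification of synthase coding sequences.

Chemotype is determined by which synthase genes encode working enzymes:
drug-type plants carry an intact THCAS reading frame but a frameshifted
CBDAS (a 4-bp deletion near position 153), fiber-type plants the reverse
situation (intact CBDAS, THCAS knocked out by a premature stop), and
intermediates carry both genes intact.  This module reproduces that
sequence-structural reading of activity: a gene copy is called ``active``
iff its translation reaches at least a threshold fraction (default 90%) of
the reference protein length and its alignment to the active reference
contains no frameshifting (length not divisible by 3) internal indel.

Catalytic-site point substitutions that alter enzyme activity without
disturbing the reading frame are deliberately not modelled; a sequence can
therefore be structurally "active" yet enzymatically dead, which is why
conflicts are surfaced as QC flags rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "IntegrityReport",
    "Indel",
    "translate_cds",
    "assess_integrity",
    "pairwise_align",
    "make_aligner",
    "DEFAULT_LENGTH_THRESHOLD",
]

DEFAULT_LENGTH_THRESHOLD = 0.90

_DNA = set("ACGT")


@dataclass(frozen=True)
class Indel:
    """An internal insertion (positive length) or deletion (negative) in
    the sample relative to the reference; ``ref_pos`` is the 1-based
    reference coordinate immediately left of the event."""

    ref_pos: int
    length: int

    @property
    def frameshifting(self) -> bool:
        return self.length % 3 != 0


@dataclass
class IntegrityReport:
    sample_id: str
    gene: str
    protein: str
    full_length: bool
    first_stop_position: int | None  # 1-based codon index of the stop
    frameshift: bool
    indels: list[Indel]
    fraction_of_reference: float
    activity_call: str  # "active" | "inactive"
    flags: list[str] = field(default_factory=list)


def translate_cds(cds: str, table: int = 1) -> tuple[str, int | None, list[str]]:
    """Translate from position 1 to the first stop codon (or sequence end).

    Returns ``(protein, first_stop_codon_index, flags)``; the stop index is
    1-based, ``None`` if no stop is reached.  A trailing partial codon is
    ignored with a ``partial_terminal_codon`` flag.
    """
    cds = cds.upper()
    if not cds or len(cds) < 3:
        raise ValueError("CDS must be at least one codon long")
    bad = set(cds) - _DNA
    if bad:
        raise ValueError(f"non-nucleotide characters in CDS: {sorted(bad)}")
    flags = []
    if len(cds) % 3:
        flags.append("partial_terminal_codon")
        cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate(table=table))
    stop = aa.find("*")
    if stop == -1:
        return aa, None, flags
    return aa[:stop], stop + 1, flags


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAligner:
    """Global affine-gap aligner with cost-free terminal gaps."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # a gap of length L scores gap_open + L * gap_extend
    aligner.open_internal_gap_score = gap_open + gap_extend
    aligner.extend_internal_gap_score = gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_align(
    seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None
) -> tuple[str, str, float]:
    """Best end-gap-free pairwise alignment as two gapped strings."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = aligner or make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1]), aln.score


def _internal_indels(alignment) -> list[Indel]:
    """Indels between consecutive aligned blocks (end gaps excluded)."""
    blocks_t, blocks_q = alignment.aligned
    indels = []
    for (t_prev, q_prev), (t_next, q_next) in zip(
        zip(blocks_t[:-1, 1], blocks_q[:-1, 1]),
        zip(blocks_t[1:, 0], blocks_q[1:, 0]),
    ):
        dt = int(t_next - t_prev)  # reference bases skipped -> deletion
        dq = int(q_next - q_prev)  # sample bases inserted -> insertion
        if dq:
            indels.append(Indel(ref_pos=int(t_prev), length=dq))
        if dt:
            indels.append(Indel(ref_pos=int(t_prev), length=-dt))
    return indels


def assess_integrity(
    sample_cds: str,
    reference_cds: str,
    length_threshold: float = DEFAULT_LENGTH_THRESHOLD,
    sample_id: str = "",
    gene: str = "",
    aligner: PairwiseAligner | None = None,
) -> IntegrityReport:
    """Classify a synthase CDS as active/inactive against an intact reference.

    The sample is aligned end-gap-free to ``reference_cds`` (which must be a
    complete ORF); internal indels of length not divisible by 3 set
    ``frameshift``.  Translation from position 1 to the first stop gives the
    protein; ``full_length`` requires at least ``length_threshold`` of the
    reference protein length and no frameshift.
    """
    if not sample_cds or not reference_cds:
        raise ValueError("empty sequence")
    ref_protein, ref_stop, _ = translate_cds(reference_cds)
    if not ref_protein:
        raise ValueError("reference CDS translates to an empty protein")
    protein, first_stop, flags = translate_cds(sample_cds)
    aligner = aligner or make_aligner()
    aln = aligner.align(reference_cds.upper(), sample_cds.upper())[0]
    indels = _internal_indels(aln)
    frameshift = any(i.frameshifting for i in indels)
    fraction = len(protein) / len(ref_protein)
    full_length = fraction >= length_threshold and not frameshift
    if first_stop is not None and fraction < length_threshold:
        flags.append("premature_stop")
    return IntegrityReport(
        sample_id=sample_id,
        gene=gene,
        protein=protein,
        full_length=full_length,
        first_stop_position=first_stop,
        frameshift=frameshift,
        indels=indels,
        fraction_of_reference=fraction,
        activity_call="active" if (full_length and not frameshift) else "inactive",
        flags=flags,
    )
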