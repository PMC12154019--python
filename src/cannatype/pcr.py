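"""In-silico allele-specific (ARMS) multiplex PCR.

The wet-lab assay this emulates distinguishes active from inactive
cannabinoid-synthase alleles with primers whose 3'-terminal base sits on a
single-nucleotide polymorphism (amplification refractory mutation system,
ARMS): a 3' mismatch blocks extension, so a band is produced only from the
matching allele.  Each gene additionally carries a non-allele-specific
internal-control amplicon guarding against false negatives.

The engine is primer-agnostic: binding is scored by mismatch counting (an
exact 3'-terminal window plus a bounded internal mismatch fraction), with
no thermodynamic model -- the assay readout being emulated is binary band
presence on an agarose gel.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Primer",
    "PrimerPair",
    "AssayDefinition",
    "BindingSite",
    "Amplicon",
    "AmpliconResult",
    "BandPattern",
    "PCRParams",
    "SpecificityReport",
    "find_binding_sites",
    "amplify",
    "run_assay",
    "validate_allele_specificity",
    "reverse_complement",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """A single oligo, written 5'->3'; IUPAC ambiguity codes allowed."""

    name: str
    sequence: str
    allele_specific: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise ValueError(f"primer {self.name}: length {len(seq)} < 15")
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC letters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: Primer
    reverse: Primer
    gene: str  # "THCAS" | "CBDAS"
    role: str  # "target" | "internal_control"
    expected_size: int

    def __post_init__(self) -> None:
        if self.expected_size <= 0:
            raise ValueError(f"pair {self.name}: expected_size must be > 0")
        if self.role not in ("target", "internal_control"):
            raise ValueError(f"pair {self.name}: unknown role {self.role!r}")


@dataclass
class AssayDefinition:
    """The multiplex marker panel: allele-specific target pairs plus
    internal controls, keyed by pair name."""

    name: str
    pairs: list[PrimerPair]

    def pair(self, name: str) -> PrimerPair:
        for p in self.pairs:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_dict(self) -> dict:
        def prim(p: Primer) -> dict:
            return {
                "name": p.name,
                "sequence": p.sequence,
                "allele_specific": p.allele_specific,
                "note": p.note,
            }

        return {
            "name": self.name,
            "pairs": [
                {
                    "name": pp.name,
                    "gene": pp.gene,
                    "role": pp.role,
                    "expected_size": pp.expected_size,
                    "forward": prim(pp.forward),
                    "reverse": prim(pp.reverse),
                }
                for pp in self.pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayDefinition":
        def prim(pd: dict) -> Primer:
            return Primer(
                name=pd["name"],
                sequence=pd["sequence"],
                allele_specific=bool(pd.get("allele_specific", False)),
                note=pd.get("note", ""),
            )

        return cls(
            name=d["name"],
            pairs=[
                PrimerPair(
                    name=pd["name"],
                    forward=prim(pd["forward"]),
                    reverse=prim(pd["reverse"]),
                    gene=pd["gene"],
                    role=pd["role"],
                    expected_size=int(pd["expected_size"]),
                )
                for pd in d["pairs"]
            ],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AssayDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PCRParams:
    """Binding stringency.

    ``three_prime_exact_window`` bases at the primer 3' end must match
    exactly (IUPAC-compatibly); elsewhere up to
    ``max_internal_mismatch_fraction`` of primer length may mismatch.
    """

    max_internal_mismatch_fraction: float = 0.10
    three_prime_exact_window: int = 1
    size_tolerance: float = 0.10
    max_product_len: int = 3000


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the template, 1-based inclusive plus-strand
    coordinates.  On '+' the primer 3' end is at ``end``; on '-' it is at
    ``start``."""

    start: int
    end: int
    strand: str  # '+' | '-'
    mismatches: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    note: str


@dataclass
class AmpliconResult:
    pair_name: str
    template_id: str
    products: list[Amplicon]


@dataclass
class BandPattern:
    sample_id: str
    presence: dict[str, bool]
    sizes: dict[str, list[int]]
    flags: list[str] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _mismatch_profile(template: np.ndarray, primer: str) -> np.ndarray:
    """Boolean (n_offsets, len(primer)) array: True where primer letter is
    incompatible with the template base at that offset+position."""
    L = len(primer)
    windows = np.lib.stride_tricks.sliding_window_view(template, L)
    mism = np.zeros(windows.shape, dtype=bool)
    for j, letter in enumerate(primer):
        allowed = np.frombuffer(IUPAC[letter].encode(), dtype=np.uint8)
        mism[:, j] = ~np.isin(windows[:, j], allowed)
    return mism


def find_binding_sites(
    template: str, primer: Primer, params: PCRParams = PCRParams()
) -> list[BindingSite]:
    """All qualifying primer footprints on both strands of ``template``.

    A site qualifies iff the 3'-terminal window matches with zero
    mismatches and the remaining (internal) positions carry at most
    ``max_internal_mismatch_fraction * len(primer)`` mismatches.
    """
    template = template.upper()
    if set(template) - set("ACGT"):
        raise ValueError("template must contain only A/C/G/T")
    L = len(primer)
    if L > len(template):
        return []
    tarr = _encode(template)
    w = params.three_prime_exact_window
    max_internal = int(np.floor(params.max_internal_mismatch_fraction * L + 1e-9))
    sites: list[BindingSite] = []
    for strand in "+-":
        seq = primer.sequence if strand == "+" else reverse_complement(primer.sequence)
        mism = _mismatch_profile(tarr, seq)
        # 3' window sits at the right end of the footprint on '+', left on '-'
        three_prime = mism[:, -w:] if strand == "+" else mism[:, :w]
        internal = mism[:, :-w] if strand == "+" else mism[:, w:]
        ok = (~three_prime.any(axis=1)) & (internal.sum(axis=1) <= max_internal)
        for off in np.nonzero(ok)[0]:
            sites.append(
                BindingSite(
                    start=int(off) + 1,
                    end=int(off) + L,
                    strand=strand,
                    mismatches=int(mism[off].sum()),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: str,
    pair: PrimerPair,
    params: PCRParams = PCRParams(),
    template_id: str = "",
) -> AmpliconResult:
    """Enumerate products of a primer pair on a template.

    A product forms for every convergent combination of a plus-strand site
    of one primer and a downstream minus-strand site of the other; it spans
    from the upstream primer's 5' end to the downstream primer's 5' end
    (primers included), up to ``params.max_product_len``.
    """
    f_sites = find_binding_sites(template, pair.forward, params)
    r_sites = find_binding_sites(template, pair.reverse, params)
    products = []
    for plus, minus, note in (
        (pair.forward, pair.reverse, "fwd(+)/rev(-)"),
        (pair.reverse, pair.forward, "rev(+)/fwd(-)"),
    ):
        plus_sites = [s for s in (f_sites if plus is pair.forward else r_sites) if s.strand == "+"]
        minus_sites = [s for s in (r_sites if plus is pair.forward else f_sites) if s.strand == "-"]
        for sp in plus_sites:
            for sm in minus_sites:
                if sm.start < sp.start or sm.end < sp.end:
                    continue  # not convergent
                length = sm.end - sp.start + 1
                if length <= params.max_product_len:
                    products.append(Amplicon(sp.start, sm.end, length, note))
    products.sort(key=lambda a: (a.start, a.end))
    return AmpliconResult(pair.name, template_id, products)


def run_assay(
    sequences: dict[str, str],
    assay: AssayDefinition,
    params: PCRParams = PCRParams(),
    sample_id: str = "",
) -> BandPattern:
    """Run every pair of the assay against a sample's gene sequences.

    ``sequences`` maps gene name (e.g. "THCAS") to its sequence.  A band is
    present iff at least one product lies within ``params.size_tolerance``
    of the pair's expected size.  A missing gene sequence yields an absent
    band plus a QC flag (so an absent internal control is visible, the way
    a failed wet-lab control lane would be).
    """
    presence: dict[str, bool] = {}
    sizes: dict[str, list[int]] = {}
    flags: list[str] = []
    for pair in assay.pairs:
        template = sequences.get(pair.gene)
        if not template:
            presence[pair.name] = False
            sizes[pair.name] = []
            flags.append(f"missing_template:{pair.gene}")
            continue
        result = amplify(template, pair, params, template_id=pair.gene)
        lens = [p.length for p in result.products]
        tol = params.size_tolerance * pair.expected_size
        matching = [n for n in lens if abs(n - pair.expected_size) <= tol]
        presence[pair.name] = bool(matching)
        sizes[pair.name] = lens
    return BandPattern(sample_id=sample_id, presence=presence, sizes=sizes, flags=flags)


@dataclass(frozen=True)
class SpecificityReport:
    binds_active: bool
    binds_inactive: bool

    @property
    def discriminating(self) -> bool:
        return self.binds_active and not self.binds_inactive


def validate_allele_specificity(
    primer: Primer,
    active_template: str,
    inactive_template: str,
    params: PCRParams = PCRParams(),
) -> SpecificityReport:
    """Design-time check that an ARMS primer binds the active allele and
    not the inactive one (or an unrelated sequence)."""
    return SpecificityReport(
        binds_active=bool(find_binding_sites(active_template, primer, params)),
        binds_inactive=bool(find_binding_sites(inactive_template, primer, params)),
    )
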