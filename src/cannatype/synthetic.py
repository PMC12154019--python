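"""Self-consistent synthetic Cannabis panels.

Generates cannabinoid tables, THCAS/CBDAS coding sequences and ground-truth
labels with the genetic architecture the downstream analysis assumes:

* drug-type (chemotype I): active THCAS (discriminating SNP in the active
  state, intact ORF) and inactive CBDAS (inactive SNP state plus a 4-bp
  frameshift deletion near position 153) -- genotype ``Td``;
* intermediate (II): both synthases active -- ``TD``;
* fiber-type (III): inactive THCAS (inactive SNP state plus an engineered
  premature stop at ~60% of the CDS) and active CBDAS -- ``tD``.

Each gene descends from one random ancestral CDS per panel; the active and
inactive allele lineages additionally diverge at a configurable background
of neutral sites (default 2%/site), emulating the dozens of substitutions
separating real active and inactive synthase alleles, and every sample
carries its own low-rate background substitutions.  Functional coordinates
(SNPs, primer footprints, start/stop codons, the deletion window) are
protected, and substitutions never create in-frame stop codons, so the
engineered activity states are exactly the truth labels.

%THC and %CBD are drawn uniformly from per-chemotype ranges whose defaults
are chosen so the three classes are linearly separable at the standard
log-ratio cutoffs (0.0 and -1.0); a guard rejects configurations whose
ranges would overlap across those cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemotype import CannabinoidRecord
from .pcr import AssayDefinition, Primer, PrimerPair, reverse_complement

__all__ = [
    "PanelConfig",
    "SyntheticSample",
    "make_panel",
    "make_reference_fixtures",
    "write_panel",
    "panel_cannabinoid_frame",
    "panel_truth_frame",
    "write_fasta",
    "read_fasta",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
PRIMER_LEN = 20

# expected band sizes (bp) of the four marker reactions
SIZE_THCASD = 384
SIZE_CBDASF = 346
SIZE_THCASINT = 291
SIZE_CBDASINT = 169

_FIXTURE_SEED = 536870911  # fixed stream for the non-random reference fixtures


@dataclass(frozen=True)
class PanelConfig:
    """Generator parameters; ``seed`` fully determines the panel."""

    n_drug: int = 70
    n_intermediate: int = 11
    n_fiber: int = 4
    # per-chemotype percent w/w ranges (min, max)
    drug_thc: tuple[float, float] = (0.3, 3.7)
    drug_cbd: tuple[float, float] = (0.001, 0.16)
    intermediate_thc: tuple[float, float] = (0.7, 1.7)
    intermediate_cbd: tuple[float, float] = (1.8, 6.5)
    fiber_thc: tuple[float, float] = (0.06, 0.15)
    fiber_cbd: tuple[float, float] = (1.6, 3.0)
    seq_length_thcas: int = 1635
    seq_length_cbdas: int = 1632
    snp_pos_thcas: int = 1349  # 1-based CDS coordinate
    snp_pos_cbdas: int = 645
    active_allele_thcas: str = "G"
    inactive_allele_thcas: str = "T"
    active_allele_cbdas: str = "C"
    inactive_allele_cbdas: str = "G"
    frameshift_pos_cbdas: int = 153
    frameshift_len: int = 4
    background_mutation_rate: float = 0.002
    allele_divergence: float = 0.02
    intergene_divergence: float = 0.16
    upper_cut: float = 0.0
    lower_cut: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def frameshift_in_frame(self) -> bool:
        """A 6-bp deletion keeps the reading frame (no frameshift)."""
        return self.frameshift_len % 3 == 0

    def validate(self) -> None:
        if min(self.n_drug, self.n_intermediate, self.n_fiber) < 0:
            raise ValueError("sample counts must be >= 0")
        ranges = {
            "drug_thc": self.drug_thc,
            "drug_cbd": self.drug_cbd,
            "intermediate_thc": self.intermediate_thc,
            "intermediate_cbd": self.intermediate_cbd,
            "fiber_thc": self.fiber_thc,
            "fiber_cbd": self.fiber_cbd,
        }
        for name, (lo, hi) in ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: require 0 < min <= max, got {(lo, hi)}")
        for length, snp, gene in (
            (self.seq_length_thcas, self.snp_pos_thcas, "THCAS"),
            (self.seq_length_cbdas, self.snp_pos_cbdas, "CBDAS"),
        ):
            if length < 1500 or length % 3:
                raise ValueError(f"{gene}: length must be >= 1500 and a multiple of 3")
            if not 1 <= snp <= length:
                raise ValueError(f"{gene}: SNP position {snp} outside sequence")
        if self.frameshift_len not in (4, 6):
            raise ValueError("frameshift_len must be 4 or 6")
        if not 1 <= self.frameshift_pos_cbdas <= self.seq_length_cbdas:
            raise ValueError("frameshift position outside CBDAS sequence")
        for allele in (
            self.active_allele_thcas,
            self.inactive_allele_thcas,
            self.active_allele_cbdas,
            self.inactive_allele_cbdas,
        ):
            if allele not in BASES:
                raise ValueError(f"allele must be one of {BASES}, got {allele!r}")
        if self.active_allele_thcas == self.inactive_allele_thcas:
            raise ValueError("THCAS active and inactive alleles must differ")
        if self.active_allele_cbdas == self.inactive_allele_cbdas:
            raise ValueError("CBDAS active and inactive alleles must differ")
        if not 0 <= self.background_mutation_rate < 0.05:
            raise ValueError("background_mutation_rate must be in [0, 0.05)")
        if not 0 < self.intergene_divergence < 0.5:
            raise ValueError("intergene_divergence must be in (0, 0.5)")
        if not 0 <= self.allele_divergence < 0.1:
            raise ValueError("allele_divergence must be in [0, 0.1)")
        # linear-separability guard at the log-ratio cutoffs
        lo, hi = self.lower_cut, self.upper_cut
        checks = [
            ("drug min log-ratio must exceed the upper cutoff",
             math.log10(self.drug_thc[0] / self.drug_cbd[1]) > hi),
            ("fiber max log-ratio must be below the lower cutoff",
             math.log10(self.fiber_thc[1] / self.fiber_cbd[0]) < lo),
            ("intermediate min log-ratio must exceed the lower cutoff",
             math.log10(self.intermediate_thc[0] / self.intermediate_cbd[1]) > lo),
            ("intermediate max log-ratio must be below the upper cutoff",
             math.log10(self.intermediate_thc[1] / self.intermediate_cbd[0]) < hi),
        ]
        bad = [msg for msg, ok in checks if not ok]
        if bad:
            raise ValueError(
                "cannabinoid ranges overlap across chemotype cutoffs: "
                + "; ".join(bad)
            )


@dataclass
class SyntheticSample:
    sample_id: str
    true_chemotype: str  # I | II | III
    cannabinoids: CannabinoidRecord
    thcas_seq: str
    cbdas_seq: str
    truth_genotype: str  # Td | TD | tD


@dataclass
class _GeneDesign:
    """One gene's engineered coordinates and assay primers."""

    gene: str
    active_seq: str
    snp_pos: int
    active_base: str
    inactive_base: str
    pairs: list[PrimerPair]
    protected: set[int]  # 1-based positions never touched by mutations
    premature_stop_codon: int | None = None  # 1-based codon index (THCAS)
    deletion: tuple[int, int] | None = None  # (pos, len) (CBDAS)


def _random_orf(rng: np.random.Generator, n_nt: int) -> list[str]:
    """ATG + random non-stop codons + TAA, as a list of bases."""
    n_codons = n_nt // 3
    seq = ["A", "T", "G"]
    while len(seq) < n_nt - 3:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            seq.extend(codon)
    seq.extend("TAA")
    return seq


def _set_codon(seq: list[str], codon_idx: int, codon: str) -> None:
    seq[(codon_idx - 1) * 3 : codon_idx * 3] = list(codon)


def _codon_at(seq: list[str], pos: int) -> tuple[int, int]:
    """(codon start index 0-based, offset within codon) for 1-based pos."""
    i = pos - 1
    return i - i % 3, i % 3


def _safe_snp_codon(seq: list[str], pos: int, base_a: str, base_b: str) -> None:
    """Ensure the codon containing ``pos`` is stop-free with either allele."""
    start, off = _codon_at(seq, pos)
    codon = seq[start : start + 3]
    for base in (base_a, base_b):
        codon[off] = base
        while "".join(codon) in STOP_CODONS:
            # replace a non-SNP position until stop-free under both alleles
            other = (off + 1) % 3
            codon[other] = "C"
            seq[start + other] = "C"
            codon = seq[start : start + 3]
            codon[off] = base
    seq[start + off] = base_a


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    rate: float,
    protected: set[int],
) -> list[str]:
    """Substitute bases at ``rate`` per site, skipping protected positions
    and never creating an in-frame stop codon."""
    if rate <= 0:
        return list(seq)
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        pos = int(i) + 1
        if pos in protected:
            continue
        start = i - i % 3
        choices = [b for b in BASES if b != out[i]]
        rng.shuffle(choices)
        for b in choices:
            codon = out[start : start + 3]
            codon[i % 3] = b
            if "".join(codon) not in STOP_CODONS:
                out[i] = b
                break
    return out


def _derive_homolog(
    rng: np.random.Generator, seq: list[str], length: int, rate: float
) -> list[str]:
    """A paralogous ORF of the requested length: truncate/extend the source
    ORF (keeping start and stop codons) and substitute at ``rate``/site."""
    out = list(seq)
    if length < len(out):
        out = out[: length - 3] + ["T", "A", "A"]
    while len(out) < length:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            out = out[:-3] + list(codon) + out[-3:]
    protected = {1, 2, 3, length - 2, length - 1, length}
    return _mutate(rng, out, rate, protected)


def _design_gene(
    rng: np.random.Generator,
    seq: list[str],
    gene: str,
    length: int,
    snp_pos: int,
    active_base: str,
    inactive_base: str,
    target_name: str,
    target_size: int,
    target_orientation: str,  # "forward" | "reverse": which primer is allele-specific
    internal_name: str,
    internal_span: tuple[int, int],
    internal_size: int,
) -> _GeneDesign:
    seq = list(seq)
    _safe_snp_codon(seq, snp_pos, active_base, inactive_base)
    footprints: list[tuple[int, int]] = []

    def substring(start: int, end: int) -> str:
        footprints.append((start, end))
        return "".join(seq[start - 1 : end])

    if target_orientation == "reverse":
        # allele-specific 3' base on the minus strand at the SNP
        rev_fp = (snp_pos, snp_pos + PRIMER_LEN - 1)
        fwd_fp_start = rev_fp[1] - target_size + 1
        fwd_fp = (fwd_fp_start, fwd_fp_start + PRIMER_LEN - 1)
        fwd = Primer(f"{target_name}-F", substring(*fwd_fp))
        rev = Primer(
            f"{target_name}-R",
            reverse_complement(substring(*rev_fp)),
            allele_specific=True,
        )
    else:
        fwd_fp = (snp_pos - PRIMER_LEN + 1, snp_pos)
        rev_fp_end = fwd_fp[0] + target_size - 1
        rev_fp = (rev_fp_end - PRIMER_LEN + 1, rev_fp_end)
        fwd = Primer(f"{target_name}-F", substring(*fwd_fp), allele_specific=True)
        rev = Primer(f"{target_name}-R", reverse_complement(substring(*rev_fp)))
    for lo, hi in footprints:
        if not (1 <= lo < hi <= length):
            raise ValueError(
                f"{gene}: primer footprint {(lo, hi)} outside 1..{length}"
            )
    target_pair = PrimerPair(
        name=target_name, forward=fwd, reverse=rev, gene=gene,
        role="target", expected_size=target_size,
    )
    int_start, int_end = internal_span
    ifwd = Primer(f"{internal_name}-F", substring(int_start, int_start + PRIMER_LEN - 1))
    irev = Primer(
        f"{internal_name}-R",
        reverse_complement(substring(int_end - PRIMER_LEN + 1, int_end)),
    )
    internal_pair = PrimerPair(
        name=internal_name, forward=ifwd, reverse=irev, gene=gene,
        role="internal_control", expected_size=internal_size,
    )
    protected = {snp_pos, 1, 2, 3, length - 2, length - 1, length}
    start, _ = _codon_at(seq, snp_pos)
    protected |= {start + 1, start + 2, start + 3}
    for lo, hi in footprints:
        protected |= set(range(lo, hi + 1))
    return _GeneDesign(
        gene=gene,
        active_seq="".join(seq),
        snp_pos=snp_pos,
        active_base=active_base,
        inactive_base=inactive_base,
        pairs=[target_pair, internal_pair],
        protected=protected,
    )


def _build_designs(config: PanelConfig, rng: np.random.Generator) -> dict[str, _GeneDesign]:
    # one random ancestral CDS per panel; the second gene is a diverged
    # paralog of the first (real THCAS/CBDAS are ~84% identical), keeping
    # cross-gene alignments and distances meaningful
    thcas_anc = _random_orf(rng, config.seq_length_thcas)
    cbdas_anc = _derive_homolog(
        rng, thcas_anc, config.seq_length_cbdas, config.intergene_divergence
    )
    thcas = _design_gene(
        rng, thcas_anc, "THCAS", config.seq_length_thcas, config.snp_pos_thcas,
        config.active_allele_thcas, config.inactive_allele_thcas,
        "THCASd", SIZE_THCASD, "reverse",
        "THCASint", (100, 390), SIZE_THCASINT,
    )
    cbdas = _design_gene(
        rng, cbdas_anc, "CBDAS", config.seq_length_cbdas, config.snp_pos_cbdas,
        config.active_allele_cbdas, config.inactive_allele_cbdas,
        "CBDASf", SIZE_CBDASF, "forward",
        "CBDASint", (300, 468), SIZE_CBDASINT,
    )
    # fiber THCAS premature stop at ~60% of the CDS, clear of footprints
    n_codons = config.seq_length_thcas // 3
    stop_codon = int(n_codons * 0.6)
    while any(
        lo <= p <= hi
        for p in range((stop_codon - 1) * 3 + 1, stop_codon * 3 + 1)
        for (lo, hi) in _footprint_ranges(thcas)
    ) or stop_codon * 3 >= config.snp_pos_thcas:
        stop_codon -= 1
    thcas.premature_stop_codon = stop_codon
    thcas.protected |= set(range((stop_codon - 1) * 3 + 1, stop_codon * 3 + 1))
    # drug CBDAS frameshift deletion window
    dpos, dlen = config.frameshift_pos_cbdas, config.frameshift_len
    if any(
        lo <= p <= hi
        for p in range(dpos, dpos + dlen)
        for (lo, hi) in _footprint_ranges(cbdas)
    ):
        raise ValueError("CBDAS deletion window collides with a primer footprint")
    cbdas.deletion = (dpos, dlen)
    cbdas.protected |= set(range(dpos, dpos + dlen))
    return {"THCAS": thcas, "CBDAS": cbdas}


def _footprint_ranges(design: _GeneDesign) -> list[tuple[int, int]]:
    # footprints were folded into ``protected``; recover contiguous runs
    pos = sorted(design.protected)
    runs = []
    run_start = prev = pos[0]
    for p in pos[1:]:
        if p != prev + 1:
            runs.append((run_start, prev))
            run_start = p
        prev = p
    runs.append((run_start, prev))
    return runs


def _apply_inactive_thcas(seq: list[str], design: _GeneDesign) -> list[str]:
    out = list(seq)
    out[design.snp_pos - 1] = design.inactive_base
    _set_codon(out, design.premature_stop_codon, "TAA")
    return out


def _apply_inactive_cbdas_snp(seq: list[str], design: _GeneDesign) -> list[str]:
    out = list(seq)
    out[design.snp_pos - 1] = design.inactive_base
    return out


def _apply_deletion(seq: list[str], deletion: tuple[int, int]) -> list[str]:
    pos, length = deletion
    return seq[: pos - 1] + seq[pos - 1 + length :]


def _reference_sequences(designs: dict[str, _GeneDesign]) -> dict[str, str]:
    thcas, cbdas = designs["THCAS"], designs["CBDAS"]
    return {
        "THCAS_active": thcas.active_seq,
        "THCAS_inactive": "".join(
            _apply_inactive_thcas(list(thcas.active_seq), thcas)
        ),
        "CBDAS_active": cbdas.active_seq,
        "CBDAS_inactive": "".join(
            _apply_deletion(
                _apply_inactive_cbdas_snp(list(cbdas.active_seq), cbdas),
                cbdas.deletion,
            )
        ),
    }


def make_reference_fixtures(
    config: PanelConfig | None = None,
) -> tuple[dict[str, str], AssayDefinition]:
    """Fixed active/inactive reference sequences plus the marker assay.

    Returns ``(sequences, assay)`` where ``sequences`` holds
    ``THCAS_active``, ``THCAS_inactive``, ``CBDAS_active`` and
    ``CBDAS_inactive`` CDSs engineered so the four marker reactions
    produce their nominal band sizes on the matching templates.  Built from
    a fixed internal stream, so the fixtures are identical across calls.
    """
    config = config or PanelConfig()
    designs = _build_designs(config, np.random.default_rng(_FIXTURE_SEED))
    thcas, cbdas = designs["THCAS"], designs["CBDAS"]
    assay = AssayDefinition(name="synthase_markers", pairs=thcas.pairs + cbdas.pairs)
    return _reference_sequences(designs), assay


def panel_references(config: PanelConfig | None = None) -> dict[str, str]:
    """The active/inactive ancestral reference CDSs of a panel.

    Rebuilt from ``config.seed`` with the same stream :func:`make_panel`
    uses, so the returned sequences are the ancestors of that panel's
    samples (each sample additionally carries its allele-lineage and
    background substitutions).
    """
    config = config or PanelConfig()
    return _reference_sequences(_build_designs(config, np.random.default_rng(config.seed)))


_RANGES = {
    "I": ("drug_thc", "drug_cbd"),
    "II": ("intermediate_thc", "intermediate_cbd"),
    "III": ("fiber_thc", "fiber_cbd"),
}
_GENOTYPE = {"I": "Td", "II": "TD", "III": "tD"}


def make_panel(
    config: PanelConfig | None = None,
) -> tuple[list[SyntheticSample], AssayDefinition]:
    """Generate a synthetic panel plus its matching assay definition.

    The panel's ancestral CDSs, allele lineages, per-sample background
    substitutions and cannabinoid draws all derive from ``config.seed``,
    so the same config yields a byte-identical panel.
    """
    config = config or PanelConfig()
    rng = np.random.default_rng(config.seed)
    designs = _build_designs(config, rng)
    thcas, cbdas = designs["THCAS"], designs["CBDAS"]
    div = config.allele_divergence
    # allele lineages: active/inactive haplotypes per gene (pre-deletion)
    hap = {
        ("THCAS", True): _mutate(rng, list(thcas.active_seq), div, thcas.protected),
        ("THCAS", False): _mutate(
            rng, _apply_inactive_thcas(list(thcas.active_seq), thcas), div, thcas.protected
        ),
        ("CBDAS", True): _mutate(rng, list(cbdas.active_seq), div, cbdas.protected),
        ("CBDAS", False): _mutate(
            rng, _apply_inactive_cbdas_snp(list(cbdas.active_seq), cbdas), div, cbdas.protected
        ),
    }
    samples: list[SyntheticSample] = []
    counter = 0
    for chemotype, n in (
        ("I", config.n_drug), ("II", config.n_intermediate), ("III", config.n_fiber)
    ):
        thc_key, cbd_key = _RANGES[chemotype]
        thc_lo, thc_hi = getattr(config, thc_key)
        cbd_lo, cbd_hi = getattr(config, cbd_key)
        for _ in range(n):
            counter += 1
            sid = f"S{counter:03d}"
            thc = float(rng.uniform(thc_lo, thc_hi))
            cbd = float(rng.uniform(cbd_lo, cbd_hi))
            thcas_active = chemotype in ("I", "II")
            cbdas_active = chemotype in ("II", "III")
            t_seq = _mutate(
                rng, hap[("THCAS", thcas_active)],
                config.background_mutation_rate, thcas.protected,
            )
            c_seq = _mutate(
                rng, hap[("CBDAS", cbdas_active)],
                config.background_mutation_rate, cbdas.protected,
            )
            if not cbdas_active:
                c_seq = _apply_deletion(c_seq, cbdas.deletion)
            samples.append(
                SyntheticSample(
                    sample_id=sid,
                    true_chemotype=chemotype,
                    cannabinoids=CannabinoidRecord(sid, round(thc, 3), round(cbd, 3)),
                    thcas_seq="".join(t_seq),
                    cbdas_seq="".join(c_seq),
                    truth_genotype=_GENOTYPE[chemotype],
                )
            )
    assay = AssayDefinition(name="synthase_markers", pairs=thcas.pairs + cbdas.pairs)
    return samples, assay


def panel_cannabinoid_frame(panel: list[SyntheticSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in panel],
            "pct_thc": [s.cannabinoids.pct_thc for s in panel],
            "pct_cbd": [s.cannabinoids.pct_cbd for s in panel],
        }
    )


def panel_truth_frame(panel: list[SyntheticSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in panel],
            "true_chemotype": [s.true_chemotype for s in panel],
            "truth_genotype": [s.truth_genotype for s in panel],
        }
    )


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_panel(
    panel: list[SyntheticSample], assay: AssayDefinition, outdir
) -> dict[str, Path]:
    """Write a panel as plain-text artifacts.

    FASTA of all gene sequences (ids ``<sample>|<gene>``), the cannabinoid
    CSV (``sample_id,pct_thc,pct_cbd``), the truth CSV and the assay YAML.
    Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "cannabinoids": outdir / "cannabinoids.csv",
        "truth": outdir / "truth.csv",
        "assay": outdir / "assay.yaml",
    }
    records = []
    for s in panel:
        records.append((f"{s.sample_id}|THCAS", s.thcas_seq))
        records.append((f"{s.sample_id}|CBDAS", s.cbdas_seq))
    write_fasta(records, paths["sequences"])
    panel_cannabinoid_frame(panel).to_csv(paths["cannabinoids"], index=False)
    panel_truth_frame(panel).to_csv(paths["truth"], index=False)
    assay.to_yaml(paths["assay"])
    return paths
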