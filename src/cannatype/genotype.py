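"""Band patterns -> allele symbols -> composite genotype -> predicted chemotype.

Dominant-marker coding: the allele-specific THCAS band present is written
``T``, absent ``t``; the allele-specific CBDAS band present is ``D``,
absent ``d``.  The composite two-letter code maps to a predicted chemotype:
``Td`` -> I (drug), ``TD`` -> II (intermediate), ``tD`` -> III (fiber).
The fourth combination ``td`` (both synthases apparently inactive) is never
observed in the survey this reproduces and is reported as undetermined.

An absent internal-control band means the negative target call is not
trustworthy.  The default (lenient) policy still calls the lowercase allele
but attaches an ``internal_control_failed`` QC flag -- matching how the
original survey retained a sample whose THCAS control lane failed -- while
``strict=True`` returns ``no_call`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pcr import BandPattern

__all__ = [
    "GenotypeCall",
    "call_gene",
    "combine_and_predict",
    "call_sample",
    "calls_to_frame",
    "COMPOSITE_TO_CHEMOTYPE",
    "TARGET_BANDS",
    "INTERNAL_BANDS",
]

NO_CALL = "no_call"
COMPOSITE_TO_CHEMOTYPE = {"Td": "I", "TD": "II", "tD": "III"}

#: canonical assay band names per gene
TARGET_BANDS = {"THCAS": "THCASd", "CBDAS": "CBDASf"}
INTERNAL_BANDS = {"THCAS": "THCASint", "CBDAS": "CBDASint"}
_SYMBOLS = {"THCAS": ("T", "t"), "CBDAS": ("D", "d")}


@dataclass
class GenotypeCall:
    sample_id: str
    thcas_allele: str  # T | t | no_call
    cbdas_allele: str  # D | d | no_call
    composite: str  # Td | TD | tD | td | no_call
    predicted_chemotype: str  # I | II | III | undetermined | no_call
    qc_flags: list[str] = field(default_factory=list)


def call_gene(
    target_band: bool, internal_band: bool, gene: str, strict: bool = False
) -> tuple[str, list[str]]:
    """Allele symbol for one gene from its target and internal-control bands."""
    try:
        upper, lower = _SYMBOLS[gene]
    except KeyError:
        raise ValueError(f"unknown gene {gene!r}") from None
    if target_band:
        return upper, []
    if internal_band:
        return lower, []
    # negative target with failed control: unreliable negative
    flag = f"internal_control_failed:{gene}"
    if strict:
        return NO_CALL, [flag]
    return lower, [flag]


def combine_and_predict(thcas_allele: str, cbdas_allele: str) -> tuple[str, str, list[str]]:
    """Composite code and predicted chemotype from the two allele symbols.

    Returns ``(composite, predicted_chemotype, qc_flags)``; a ``no_call``
    allele propagates to a ``no_call`` composite and prediction.
    """
    if NO_CALL in (thcas_allele, cbdas_allele):
        return NO_CALL, NO_CALL, []
    if thcas_allele not in "Tt" or cbdas_allele not in "Dd":
        raise ValueError(
            f"invalid allele symbols ({thcas_allele!r}, {cbdas_allele!r})"
        )
    composite = thcas_allele + cbdas_allele
    if composite in COMPOSITE_TO_CHEMOTYPE:
        return composite, COMPOSITE_TO_CHEMOTYPE[composite], []
    return composite, "undetermined", ["atypical_genotype"]


def call_sample(pattern: BandPattern, strict: bool = False) -> GenotypeCall:
    """Full genotype call from one sample's multiplex band pattern."""
    flags = list(pattern.flags)
    alleles = {}
    for gene in ("THCAS", "CBDAS"):
        sym, f = call_gene(
            pattern.presence.get(TARGET_BANDS[gene], False),
            pattern.presence.get(INTERNAL_BANDS[gene], False),
            gene,
            strict=strict,
        )
        alleles[gene] = sym
        flags.extend(f)
    composite, predicted, f = combine_and_predict(alleles["THCAS"], alleles["CBDAS"])
    flags.extend(f)
    return GenotypeCall(
        sample_id=pattern.sample_id,
        thcas_allele=alleles["THCAS"],
        cbdas_allele=alleles["CBDAS"],
        composite=composite,
        predicted_chemotype=predicted,
        qc_flags=flags,
    )


def calls_to_frame(calls: list[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "thcas": [c.thcas_allele for c in calls],
            "cbdas": [c.cbdas_allele for c in calls],
            "composite": [c.composite for c in calls],
            "predicted_chemotype": [c.predicted_chemotype for c in calls],
            "flags": [";".join(c.qc_flags) for c in calls],
        }
    )
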