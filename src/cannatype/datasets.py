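"""Packaged reference data.

The package ships the published survey of 85 Cannabis sativa samples
(46 cultivars): per-sample %THC and %CBD (UPLC, percent w/w), the reported
log10(%THC/%CBD), the reported chemotype class, and the wet-lab
allele-specific PCR genotype letters (T/t for THCAS, D/d for CBDAS).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chemotype import CannabinoidRecord

__all__ = ["load_reference_panel", "reference_records"]


def load_reference_panel() -> pd.DataFrame:
    """The 85-sample chemotype/genotype survey table as a DataFrame.

    Columns: ``sample_id``, ``pct_thc``, ``pct_cbd``, ``log_ratio`` (as
    reported, 3 d.p.), ``chemotype`` (I/II/III), ``thcas`` (T/t),
    ``cbdas`` (D/d).
    """
    ref = resources.files("cannatype") / "data" / "reference_panel.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"sample_id": str})
    return df


def reference_records() -> list[CannabinoidRecord]:
    """The reference panel's cannabinoid columns as records."""
    df = load_reference_panel()
    return [
        CannabinoidRecord(r.sample_id, r.pct_thc, r.pct_cbd)
        for r in df.itertuples(index=False)
    ]
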