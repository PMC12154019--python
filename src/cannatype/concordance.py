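"""Chemotype-genotype concordance.

Joins the chemotype calls (from cannabinoid quantitation) with the
genotype-predicted chemotypes (from the allele-specific markers) and
reports per-sample matches plus the summary accuracy -- the headline
statistic of the marker panel (100%, 85/85, on the published survey).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chemotype import ChemotypeCall
from .genotype import GenotypeCall

__all__ = ["ConcordanceTable", "build_concordance"]


@dataclass
class ConcordanceTable:
    rows: pd.DataFrame  # sample_id, chemotype, composite, predicted_chemotype, match
    n_total: int
    n_match: int
    chemotype_counts: dict[str, int]
    composite_counts: dict[str, int]
    n_undetermined: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_match / self.n_total

    def summary(self) -> str:
        lines = [
            f"samples: {self.n_total}",
            f"matches: {self.n_match} "
            f"({self.accuracy_percent:.1f}%)",
            "chemotype counts: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.chemotype_counts.items())),
            "genotype counts:  "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.composite_counts.items())),
        ]
        if self.n_undetermined:
            lines.append(f"undetermined genotype predictions: {self.n_undetermined}")
        return "\n".join(lines)


def build_concordance(
    chemo_calls: list[ChemotypeCall], geno_calls: list[GenotypeCall]
) -> ConcordanceTable:
    """Row-wise match table between chemotype and genotype predictions.

    Both inputs must cover exactly the same sample ids.  A genotype
    prediction of ``undetermined`` (the never-observed ``td`` pattern) or
    ``no_call`` counts as a non-match and is tallied separately.
    """
    if not chemo_calls or not geno_calls:
        raise ValueError("empty input")
    chemo = {c.sample_id: c for c in chemo_calls}
    geno = {g.sample_id: g for g in geno_calls}
    if len(chemo) != len(chemo_calls) or len(geno) != len(geno_calls):
        raise ValueError("duplicate sample ids")
    only_chemo = sorted(set(chemo) - set(geno))
    only_geno = sorted(set(geno) - set(chemo))
    if only_chemo or only_geno:
        raise ValueError(
            f"sample id mismatch: chemotype-only={only_chemo}, genotype-only={only_geno}"
        )
    ids = sorted(chemo)
    records = []
    for sid in ids:
        c, g = chemo[sid], geno[sid]
        records.append(
            {
                "sample_id": sid,
                "chemotype": c.chemotype,
                "composite": g.composite,
                "predicted_chemotype": g.predicted_chemotype,
                "match": "Y" if g.predicted_chemotype == c.chemotype else "N",
            }
        )
    rows = pd.DataFrame.from_records(records)
    chemotype_counts = rows["chemotype"].value_counts().to_dict()
    composite_counts = rows["composite"].value_counts().to_dict()
    n_undet = int((rows["predicted_chemotype"] == "undetermined").sum())
    return ConcordanceTable(
        rows=rows,
        n_total=len(rows),
        n_match=int((rows["match"] == "Y").sum()),
        chemotype_counts={k: int(v) for k, v in chemotype_counts.items()},
        composite_counts={k: int(v) for k, v in composite_counts.items()},
        n_undetermined=n_undet,
    )
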