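"""Worked-example summaries over the packaged variant and clinical tables.

The packaged TSVs transcribe published per-cohort genotype counts for the
candidate gene's rare non-synonymous variants, plus a clinical feature
table.  Multi-variant individuals are encoded explicitly as carrier groups
so carrier counts can be deduplicated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "load_variant_table",
    "load_carrier_groups",
    "load_clinical_table",
    "load_reported_constants",
    "summarize_variant_table",
    "summarize_clinical_table",
    "VariantTableSummary",
]

ALLOWED_FUNCTIONAL_LABELS = ("Normal", "Reduced", "Loss")
COHORT_COLUMNS = ("misc_icl", "misc_hge", "covid19")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("burdensim").joinpath("data", name)))


def load_variant_table(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _data_path("variant_table.tsv")
    df = pd.read_csv(path, sep="\t", na_values=["-"], keep_default_na=False)
    bad = set(df["functional"]) - set(ALLOWED_FUNCTIONAL_LABELS)
    if bad:
        raise ValueError(
            f"unknown functional labels {sorted(bad)}; "
            f"allowed: {set(ALLOWED_FUNCTIONAL_LABELS)}"
        )
    return df


def load_carrier_groups(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _data_path("variant_table_carrier_groups.tsv")
    df = pd.read_csv(path, sep="\t")
    df["members"] = df["variants"].str.split("+")
    return df


def load_clinical_table(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _data_path("clinical_table.tsv")
    return pd.read_csv(path, sep="\t")


def load_reported_constants(path: str | Path | None = None) -> dict:
    path = path or _data_path("reported_constants.json")
    return json.loads(Path(path).read_text())


@dataclass
class VariantTableSummary:
    variants_by_cohort: dict[str, set[str]]
    counts_by_cohort: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]
    misc_union: set[str]
    misc_union_count: int
    counts_by_domain: dict[str, int]
    counts_by_functional: dict[str, int]
    impaired_variant_count: int
    carriers_by_cohort: dict[str, int]
    misc_carrier_total: int
    impaired_misc_carrier_tally: int


def summarize_variant_table(
    table: pd.DataFrame | None = None,
    carrier_groups: pd.DataFrame | None = None,
) -> VariantTableSummary:
    """Recompute the worked-example counts from the packaged variant table.

    Carrier counts per cohort deduplicate individuals via the carrier-group
    annotations (an individual carrying k variants appears in k genotype
    count cells but is one carrier).  The impaired-carrier tally, by
    contrast, sums per-variant patient counts over functionally impaired
    (Reduced/Loss) variants across the two case cohorts, matching how the
    published total was tabulated.
    """
    df = load_variant_table() if table is None else table
    groups = load_carrier_groups() if carrier_groups is None else carrier_groups

    variants_by_cohort = {
        c: set(df.loc[df[c] > 0, "variant"]) for c in COHORT_COLUMNS
    }
    counts_by_cohort = {c: len(s) for c, s in variants_by_cohort.items()}
    pairwise_overlap = {
        (a, b): len(variants_by_cohort[a] & variants_by_cohort[b])
        for i, a in enumerate(COHORT_COLUMNS)
        for b in COHORT_COLUMNS[i + 1:]
    }
    misc_union = variants_by_cohort["misc_icl"] | variants_by_cohort["misc_hge"]

    counts_by_domain = df.groupby("domain", dropna=False)["variant"].count().to_dict()
    counts_by_functional = df.groupby("functional")["variant"].count().to_dict()
    impaired = df["functional"].isin(["Reduced", "Loss"])

    carriers_by_cohort = {}
    for c in ("misc_icl", "misc_hge", "covid19"):
        tally = int(df[c].sum())
        extra = 0
        for _, g in groups[groups["cohort"] == c].iterrows():
            extra += len(g["members"]) - 1
        carriers_by_cohort[c] = tally - extra

    impaired_tally = int(df.loc[impaired, "misc_icl"].sum() + df.loc[impaired, "misc_hge"].sum())

    return VariantTableSummary(
        variants_by_cohort=variants_by_cohort,
        counts_by_cohort=counts_by_cohort,
        pairwise_overlap=pairwise_overlap,
        misc_union=misc_union,
        misc_union_count=len(misc_union),
        counts_by_domain=counts_by_domain,
        counts_by_functional=counts_by_functional,
        impaired_variant_count=int(impaired.sum()),
        carriers_by_cohort=carriers_by_cohort,
        misc_carrier_total=carriers_by_cohort["misc_icl"] + carriers_by_cohort["misc_hge"],
        impaired_misc_carrier_tally=impaired_tally,
    )


def summarize_clinical_table(table: pd.DataFrame | None = None) -> dict:
    """Per-column symptom rates from the clinical table fixture."""
    df = load_clinical_table() if table is None else table
    meta = df[(df["section"] == "meta") & (df["field"] == "cohort_size")]
    if meta.empty:
        raise ValueError("clinical table is missing the meta/cohort_size row")
    sizes = {c: int(meta.iloc[0][c]) for c in ("misc_n", "btnl8_n", "iei_n")}
    symptoms = df[df["section"] == "symptoms"].set_index("field")
    rates = {
        col: {
            field: 100.0 * int(symptoms.loc[field, col]) / sizes[col]
            for field in symptoms.index
        }
        for col in sizes
    }
    return {"cohort_sizes": sizes, "symptom_rates_percent": rates}
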