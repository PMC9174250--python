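"""Packaged reference tables for the anti-cancer drug / SCCO2 benchmark.

Three small tables ship with the package:

* ``dataset_summary`` — per-drug operating envelopes (T, P, rho ranges),
  solubility ranges and measurement counts for the twelve published
  anti-cancer drug solubility studies (316 measurements in total);
* ``reference_coefficients`` — the published adjusted coefficients of the
  modified Arrhenius correlation for each drug, stored in natural units;
* ``reference_aard`` — the published per-drug AARD% of all eleven
  correlations, plus the published pooled "overall" row.

These support the comparison/ranking machinery and the package's
self-checks; the underlying raw measurements live in the original
experimental studies and are not distributed here.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .correlations import CatalogueError, CoefficientSet

__all__ = [
    "DRUG_IDS",
    "normalize_drug",
    "dataset_summary",
    "reference_aard",
    "reference_overall_aard",
    "reference_coefficients",
    "load_reference_coefficients",
    "fixtures",
]

DRUG_IDS = (
    "sorafenib-tosylate",
    "sunitinib-malate",
    "azathioprine",
    "busulfan",
    "tamoxifen",
    "letrozole",
    "tamsulosin",
    "capecitabine",
    "paclitaxel",
    "5-fluorouracil",
    "thymidine",
    "decitabine",
)


def normalize_drug(drug_id: str) -> str:
    """Canonicalise a drug label ("Sorafenib tosylate" -> "sorafenib-tosylate")."""
    key = str(drug_id).strip().lower().replace("_", "-").replace(" ", "-")
    if key not in DRUG_IDS:
        raise CatalogueError(
            f"unknown drug {drug_id!r}; known: {', '.join(DRUG_IDS)}"
        )
    return key


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("sccosol").joinpath("refdata", name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def dataset_summary() -> pd.DataFrame:
    """Per-drug envelope/count table, indexed by drug_id."""
    return _read_csv("dataset_summary.csv").set_index("drug_id")


def reference_aard() -> pd.DataFrame:
    """Published per-drug AARD% matrix (12 drugs x 11 correlations)."""
    df = _read_csv("reference_aard.csv").set_index("drug_id")
    return df.drop(index="overall")


def reference_overall_aard() -> pd.Series:
    """Published pooled AARD% per correlation (the printed "overall" row)."""
    df = _read_csv("reference_aard.csv").set_index("drug_id")
    return df.loc["overall"]


def reference_coefficients() -> dict:
    """Raw packaged coefficient document (natural units) as a dict."""
    with resources.files("sccosol").joinpath(
        "refdata", "reference_coefficients.json"
    ).open("r") as fh:
        return json.load(fh)


def load_reference_coefficients(drug_id: str) -> CoefficientSet:
    """Published modified-Arrhenius coefficients for one drug, natural units."""
    doc = reference_coefficients()
    key = normalize_drug(drug_id)
    return CoefficientSet(
        model_id=doc["model"],
        drug_id=key,
        a=tuple(doc["coefficients"][key]),
        provenance="published",
    )


def fixtures() -> dict:
    """All packaged tables in one mapping (summary, coefficients, AARD)."""
    return {
        "dataset_summary": dataset_summary(),
        "reference_coefficients": reference_coefficients(),
        "reference_aard": reference_aard(),
        "reference_overall_aard": reference_overall_aard(),
    }
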