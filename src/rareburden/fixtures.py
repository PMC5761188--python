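"""Packaged machine-readable study tables.

Four small TSVs ship with the package: the 56-gene candidate manifest with
its risk-SNP links, the loss-of-function variant list with per-cohort
carrier counts and reference-database frequencies, the per-gene and
gene-set carrier counts with their published statistics, and the
prediction-stratified missense carrier counts. Frequencies printed as
"< 0.0001" load as 5e-05 (below the printed precision but distinguishable
from both 0 and absence).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .io import read_gene_manifest
from .types import GeneRecord

# printed consequence label -> controlled-vocabulary term
CONSEQUENCE_TERMS = {
    "Stop-gained": "stop_gained",
    "Frame shift": "frameshift_variant",
    "Splice donor": "splice_donor_variant",
    "Splice acceptor": "splice_acceptor_variant",
}

N_CASES = 1043
N_CONTROLS = 944

BELOW_PRECISION_MAF = 5e-05  # stand-in value for a "< 0.0001" cell


def _data_path(name: str):
    return resources.files("rareburden").joinpath("data", name)


@dataclass(frozen=True)
class LofFixtureVariant:
    """One loss-of-function variant row with its per-cohort carrier counts."""

    symbol: str
    cds_change: str
    protein_change: Optional[str]
    dbsnp_id: Optional[str]
    case_carriers: int
    control_carriers: int
    consequence_label: str
    evs_european_maf: Optional[float]
    exac_nfe_maf: Optional[float]

    @property
    def consequence_term(self) -> str:
        return CONSEQUENCE_TERMS[self.consequence_label]


def load_gene_manifest() -> list[GeneRecord]:
    """The packaged 56-gene candidate manifest (35 GWAS-proposed + 21 neighbouring)."""
    with resources.as_file(_data_path("gene_manifest.tsv")) as p:
        return read_gene_manifest(p)


def _parse_maf(cell: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    if cell.startswith("<"):
        return BELOW_PRECISION_MAF
    return float(cell)


def load_lof_fixture() -> list[LofFixtureVariant]:
    """The packaged loss-of-function variant list (38 variants, 39 carriers)."""
    with resources.as_file(_data_path("lof_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LofFixtureVariant(
                symbol=row.symbol,
                cds_change=row.cds_change,
                protein_change=None if row.protein_change == "-" else row.protein_change,
                dbsnp_id=None if row.dbsnp_id == "-" else row.dbsnp_id,
                case_carriers=int(row.case_carriers),
                control_carriers=int(row.control_carriers),
                consequence_label=row.consequence,
                evs_european_maf=_parse_maf(row.evs_european_maf),
                exac_nfe_maf=_parse_maf(row.exac_nfe_maf),
            )
        )
    return out


def load_gene_carrier_counts() -> pd.DataFrame:
    """Per-gene LoF / missense carrier counts and published statistics.

    Blank LoF cells (genes with no LoF variant in either cohort) load as
    missing; counts for those genes are zero by construction.
    """
    with resources.as_file(_data_path("gene_carrier_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"gene": str, "criterion": str})


def load_set_carrier_counts() -> pd.DataFrame:
    """Gene-set (GWAS-proposed / neighbouring / total) carrier counts."""
    with resources.as_file(_data_path("set_carrier_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_prediction_strata() -> pd.DataFrame:
    """Missense carrier counts stratified by in-silico prediction tool."""
    with resources.as_file(_data_path("prediction_strata.tsv")) as p:
        return pd.read_csv(p, sep="\t")
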