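"""Bundled published characterisation tables for the Amur sturgeon gonad
transcriptome (used as fixture inputs for bookkeeping checks).

Three small tables ship with the package:

* ``sox9_characterization`` — per-variant full length, ORF, UTR, protein
  length and molecular weight of the Sox9 transcript panel;
* ``panel_genes`` — the 60-gene early-gametogenesis panel with the reported
  tissue bias direction of each gene (ovary / testis / none);
* ``expression_bookkeeping`` — the reported category and abundance-bin
  component counts of the corpus-level expression classification.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("gonadiso.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def sox9_characterization() -> pd.DataFrame:
    return _load("sox9_characterization.tsv")


def panel_genes() -> pd.DataFrame:
    return _load("panel_genes.tsv")


def expression_bookkeeping() -> pd.DataFrame:
    return _load("expression_bookkeeping.tsv")


def verify_protein_arithmetic(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check the two protein-record identities on each characterisation row:
    5'UTR + ORF + 3'UTR == full length, and ORF/3 - 1 == amino acids."""
    if table is None:
        table = sox9_characterization()
    out = table.copy()
    out["length_sum_ok"] = (
        out["utr5_bp"] + out["orf_bp"] + out["utr3_bp"] == out["full_length_bp"])
    out["aa_ok"] = (out["orf_bp"] // 3 - 1 == out["amino_acids"])
    return out


def bookkeeping_totals(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Aggregate the component counts into the reported corpus totals."""
    if table is None:
        table = expression_bookkeeping()
    g = table.groupby("quantity")["value"].sum()
    return {
        "ovary_specific_total": int(g["ovary_specific"]),
        "testis_specific_total": int(g["testis_specific"]),
        "not_expressed_total": int(g["not_expressed"]),
        "deu_total": int(g["deu"]),
        "de_lncrna_total": int(g["de_lncrna"]),
    }


def panel_de_crossing(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Cross the panel with the reported per-gene DE directions."""
    if table is None:
        table = panel_genes()
    de = table[table["de_direction"] != "none"]
    return {
        "panel_genes": int(len(table)),
        "panel_de_genes": int(len(de)),
        "panel_ovary_up": int((de["de_direction"] == "ovary").sum()),
        "panel_testis_up": int((de["de_direction"] == "testis").sum()),
    }
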