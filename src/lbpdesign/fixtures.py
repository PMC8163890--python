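"""Packaged GUT-103 (17 strains) and GUT-108 (11 strains) function tables.

The fixtures encode only what the published overview tables print: per strain,
the SCFA/GABA/indole synthesis marks, siderophore synthesis/uptake notes,
bile-acid enzyme codes (CGH, 3a/7a/7b-HSD, 7a/7b-DH, 3a-DH, 3-oxo-5a, LCD,
SBS, taurine uptake), and bacteriocin/lantipeptide notes.  Metabolic models
are NOT part of the printed tables, so fixture candidates carry no models and
model-dependent checks must stay disabled when verifying them.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .catalog import (
    AnnotationRow,
    AnnotationTable,
    default_catalog,
    profile_functions,
)
from .designer import Candidate, CandidateSet

FIXTURES = ("gut103", "gut108")

#: headline therapeutic functions of the two consortium designs
HEADLINE_FUNCTIONS = {
    "gut103": ("butyrate", "propionate", "indole", "siderophore", "bile_salt", "antimicrobial"),
    "gut108": ("butyrate", "propionate", "gaba", "indole", "siderophore", "bile_salt", "antimicrobial"),
}

# expansion of a "+" mark into a representative annotation product phrase
_PLUS_PRODUCTS = {
    "butyrate": "butyrate kinase",
    "propionate": "methylmalonyl-CoA decarboxylase",
    "gaba": "glutamate decarboxylase",
    "indole": "tryptophanase",
}
_TEXT_COLUMNS = ("siderophore", "bile_acid", "antimicrobial")


def _fixture_frame(name: str) -> pd.DataFrame:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = importlib.resources.files("lbpdesign.data") / f"{name}.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def fixture_annotation_tables(name: str) -> list[AnnotationTable]:
    """One annotation table per strain, expanded from the printed marks."""
    frame = _fixture_frame(name)
    tables = []
    for _, row in frame.iterrows():
        sid = row["strain_id"]
        products: list[str] = []
        for col, phrase in _PLUS_PRODUCTS.items():
            if row[col].strip() == "+":
                products.append(phrase)
        for col in _TEXT_COLUMNS:
            products.extend(p.strip() for p in row[col].split(";") if p.strip())
        rows = [
            AnnotationRow(f"{sid.replace(' ', '_')}_{i:02d}", product)
            for i, product in enumerate(products, start=1)
        ]
        tables.append(AnnotationTable(strain_id=sid, rows=rows))
    return tables


def load_fixture(name: str) -> CandidateSet:
    """Fixture as a CandidateSet (profiles only; models absent).

    The printed marks are expanded into annotation product phrases and profiled
    against the shipped function catalog, so fixture presence calls flow
    through the same matching machinery as any annotation table.
    """
    frame = _fixture_frame(name)
    tables = fixture_annotation_tables(name)
    profile = profile_functions(tables, default_catalog())
    candidates = {}
    metadata = {}
    for _, row in frame.iterrows():
        sid = row["strain_id"]
        candidates[sid] = Candidate(
            strain_id=sid,
            functions=profile.functions_of(sid),
            auxotrophic_for=set(),
            secretes=set(),
            exclusion=None,
            model=None,
        )
        metadata[sid] = {"family": row["family"], "accession": row["accession"]}
    return CandidateSet(candidates=candidates, profile=profile, metadata=metadata)
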