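"""Therapeutic-function profiling of strain annotation tables.

A :class:`FunctionCatalog` encodes each therapeutic function (butyrate,
propionate, indole, siderophore synthesis/uptake, bacteriocin, bile-acid
enzymes, ...) as marker groups of annotation terms.  A function is present in
a strain when at least ``min_groups_required`` groups each have a matching
term (AND over groups, OR within a group); a term matches a feature by
case-insensitive substring on the product text or by exact term-id match.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
import yaml

EXCLUSION_CATEGORIES = ("transferable_AMR", "virulence_factor")


class CatalogError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class FunctionDef:
    function_id: str
    display_name: str
    #: each group is a tuple of annotation terms/patterns (OR within a group)
    marker_groups: tuple[tuple[str, ...], ...]
    #: groups that must match; defaults to all groups
    min_groups_required: int | None = None

    def __post_init__(self):
        if not self.marker_groups:
            raise CatalogError(f"function {self.function_id!r} has no marker groups")
        for g in self.marker_groups:
            if not g or any(not t for t in g):
                raise CatalogError(
                    f"function {self.function_id!r} has an empty marker group or term"
                )

    @property
    def required(self) -> int:
        return (
            len(self.marker_groups)
            if self.min_groups_required is None
            else self.min_groups_required
        )


@dataclass
class FunctionCatalog:
    functions: list[FunctionDef]

    def __post_init__(self):
        ids = [f.function_id for f in self.functions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate function ids: {dup}")

    @property
    def function_ids(self) -> list[str]:
        return [f.function_id for f in self.functions]

    def get(self, function_id: str) -> FunctionDef:
        for f in self.functions:
            if f.function_id == function_id:
                return f
        raise KeyError(function_id)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "FunctionCatalog":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        functions = []
        for entry in doc["functions"]:
            functions.append(
                FunctionDef(
                    function_id=entry["function_id"],
                    display_name=entry.get("display_name", entry["function_id"]),
                    marker_groups=tuple(
                        tuple(str(t) for t in group) for group in entry["marker_groups"]
                    ),
                    min_groups_required=entry.get("min_groups_required"),
                )
            )
        return cls(functions)


def default_catalog() -> FunctionCatalog:
    """The shipped catalog covering the GUT-103/GUT-108 function codes."""
    ref = importlib.resources.files("lbpdesign.data") / "function_catalog.yaml"
    with ref.open() as fh:
        return FunctionCatalog.from_yaml(fh)


@dataclass(frozen=True)
class AnnotationRow:
    feature_id: str
    product: str
    term_ids: tuple[str, ...] = ()


@dataclass
class AnnotationTable:
    strain_id: str
    rows: list[AnnotationRow]

    def __post_init__(self):
        ids = [r.feature_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(
                f"strain {self.strain_id!r}: duplicate feature ids {dup}"
            )
        for r in self.rows:
            if not r.product and not r.term_ids:
                raise AnnotationError(
                    f"strain {self.strain_id!r}, feature {r.feature_id!r}: "
                    "empty product requires term_ids"
                )


def load_annotation_table(path, format: str = "tsv", strain_id: str | None = None) -> AnnotationTable:
    """Read a strain annotation table from TSV or GFF3.

    TSV columns: feature_id, product, terms (comma-separated, may be empty).
    GFF3: CDS features carrying a ``product=`` attribute.
    """
    path = str(path)
    if strain_id is None:
        strain_id = path.rsplit("/", 1)[-1].split(".")[0]
    if format == "tsv":
        return _load_tsv(path, strain_id)
    if format == "gff3":
        return _load_gff3(path, strain_id)
    raise ValueError(f"unknown annotation format {format!r}")


def _load_tsv(path: str, strain_id: str) -> AnnotationTable:
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip().lower() for p in parts]
                if header[:2] != ["feature_id", "product"]:
                    raise AnnotationError(
                        f"{path}:{lineno}: header must start with "
                        "'feature_id<TAB>product' (optionally 'terms')"
                    )
                continue
            if len(parts) not in (2, 3):
                raise AnnotationError(f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}")
            terms = tuple(t for t in parts[2].split(",") if t) if len(parts) == 3 else ()
            rows.append(AnnotationRow(parts[0], parts[1], terms))
    return AnnotationTable(strain_id=strain_id, rows=rows)


def _load_gff3(path: str, strain_id: str) -> AnnotationTable:
    from gffutils.iterators import DataIterator

    rows = []
    counter = 0
    for feature in DataIterator(path):
        if feature.featuretype != "CDS":
            continue
        products = feature.attributes.get("product", [])
        if not products:
            continue
        fid = feature.attributes.get("ID", [None])[0]
        if fid is None:
            counter += 1
            fid = f"cds_{counter}"
        terms = tuple(feature.attributes.get("Ontology_term", []))
        rows.append(AnnotationRow(fid, products[0], terms))
    return AnnotationTable(strain_id=strain_id, rows=rows)


# ---------------------------------------------------------------------------
# Profiling


@dataclass(frozen=True)
class Evidence:
    group_index: int
    term: str
    feature_id: str


@dataclass
class FunctionProfile:
    """Strain x function presence matrix with per-cell matched evidence."""

    presence: pd.DataFrame  # bool, index = strains, columns = function_ids
    evidence: dict[tuple[str, str], tuple[Evidence, ...]]

    def __post_init__(self):
        for (s, f), ev in self.evidence.items():
            if self.presence.loc[s, f] and not ev:
                raise CatalogError(f"presence without evidence for ({s}, {f})")

    @property
    def strains(self) -> list[str]:
        return list(self.presence.index)

    @property
    def functions(self) -> list[str]:
        return list(self.presence.columns)

    def has_function(self, strain_id: str, function_id: str) -> bool:
        return bool(self.presence.loc[strain_id, function_id])

    def functions_of(self, strain_id: str) -> set[str]:
        row = self.presence.loc[strain_id]
        return set(row.index[row])

    def subset(self, strains: list[str]) -> "FunctionProfile":
        return FunctionProfile(
            presence=self.presence.loc[strains].copy(),
            evidence={k: v for k, v in self.evidence.items() if k[0] in strains},
        )


def _term_matches(term: str, row: AnnotationRow) -> bool:
    return term.lower() in row.product.lower() or term in row.term_ids


def profile_functions(
    tables: list[AnnotationTable], catalog: FunctionCatalog
) -> FunctionProfile:
    """Match the catalog's marker groups against each strain's annotations."""
    if not tables:
        raise AnnotationError("no annotation tables supplied")
    if not catalog.functions:
        raise CatalogError("empty function catalog")
    strains = [t.strain_id for t in tables]
    presence = pd.DataFrame(
        False, index=strains, columns=catalog.function_ids, dtype=bool
    )
    evidence: dict[tuple[str, str], tuple[Evidence, ...]] = {}
    for table in tables:
        for fdef in catalog.functions:
            hits: list[Evidence] = []
            groups_hit = 0
            for gi, group in enumerate(fdef.marker_groups):
                group_hits = [
                    Evidence(gi, term, row.feature_id)
                    for term in group
                    for row in table.rows
                    if _term_matches(term, row)
                ]
                if group_hits:
                    groups_hit += 1
                    hits.extend(group_hits)
            present = groups_hit >= fdef.required
            presence.loc[table.strain_id, fdef.function_id] = present
            evidence[(table.strain_id, fdef.function_id)] = (
                tuple(hits) if present else ()
            )
    return FunctionProfile(presence=presence, evidence=evidence)


def redundancy_counts(
    profile: FunctionProfile, required: set[str]
) -> dict[str, int]:
    """Number of carrier strains per required function."""
    unknown = sorted(set(required) - set(profile.functions))
    if unknown:
        raise KeyError(f"unknown function ids: {unknown}")
    return {f: int(profile.presence[f].sum()) for f in sorted(required)}


# ---------------------------------------------------------------------------
# Exclusion screening


@dataclass(frozen=True)
class ExclusionFlag:
    category: str
    term: str
    feature_id: str

    def __post_init__(self):
        if self.category not in EXCLUSION_CATEGORIES:
            raise CatalogError(f"unknown exclusion category {self.category!r}")


@dataclass
class ExclusionReport:
    strain_id: str
    flags: list[ExclusionFlag]

    @property
    def passed(self) -> bool:
        return not self.flags


def default_exclusion_terms() -> dict[str, list[str]]:
    ref = importlib.resources.files("lbpdesign.data") / "exclusion_terms.yaml"
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return {k: [str(t) for t in v] for k, v in doc.items()}


def screen_exclusions(
    table: AnnotationTable, exclusion_terms: dict[str, list[str]] | None = None
) -> ExclusionReport:
    """Flag annotations matching transferable-AMR or virulence term lists."""
    if exclusion_terms is None:
        exclusion_terms = default_exclusion_terms()
    missing = sorted(set(EXCLUSION_CATEGORIES) - set(exclusion_terms))
    if missing:
        raise CatalogError(f"exclusion catalog missing categories: {missing}")
    flags = []
    for category in EXCLUSION_CATEGORIES:
        for term in exclusion_terms[category]:
            for row in table.rows:
                if _term_matches(term, row):
                    flags.append(ExclusionFlag(category, term, row.feature_id))
    return ExclusionReport(strain_id=table.strain_id, flags=flags)
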