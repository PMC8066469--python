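"""Readers, writers and validated in-memory containers for all tabular data.

Every table the pipeline touches is strict TSV (UTF-8, ``#``-prefixed comment
lines ignored).  Missing cells are errors, never zeros — silent zero-fill
would corrupt presence/absence analysis downstream.  Feature identifiers are
case-sensitive exact strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

LAYERS = ("metagenome", "metaproteome")
FEATURE_KINDS = ("taxon", "go_term", "protein")

#: Ordered taxonomic ranks used throughout; lineages run Kingdom -> Class and
#: may be truncated (a protein annotated only to phylum has a 2-rank lineage).
RANKS = ("Kingdom", "Phylum", "Class")

UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """An input violated a structural invariant (negative count, duplicate id...)."""


class ParseError(ValueError):
    """A file could not be parsed into the expected schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library or mass-spectrometry run.

    Runs sharing a ``tech_replicate_group`` are repeat injections of the same
    biological sample and are averaged before analysis.
    """

    sample_id: str
    day: int
    treatment: str
    tank: str
    layer: str
    tech_replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"sample {self.sample_id!r}: layer must be one of {LAYERS}, got {self.layer!r}"
            )
        if self.layer == "metaproteome" and not self.tech_replicate_group:
            raise ValidationError(
                f"metaproteome run {self.sample_id!r} has no tech_replicate_group"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One inferred protein with its evidence and per-run spectral counts.

    ``probability`` is a ProteinProphet-style posterior computed upstream;
    ``unique_peptides`` is pooled across all runs.
    """

    protein_id: str
    length: int
    probability: float
    unique_peptides: int
    spectral_counts: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: length must be >= 1, got {self.length}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"protein {self.protein_id!r}: probability {self.probability} outside [0, 1]"
            )
        if self.unique_peptides < 0:
            raise ValidationError(
                f"protein {self.protein_id!r}: negative unique_peptides"
            )
        for run, c in self.spectral_counts.items():
            if c < 0:
                raise ValidationError(
                    f"protein {self.protein_id!r}: negative spectral count in run {run!r}"
                )


@dataclass
class CountTable:
    """Feature x sample matrix of nonnegative counts for one omics layer.

    ``data`` rows are features, columns are samples.  Raw counts are integers;
    real values appear after technical-replicate averaging or normalization.
    All-zero rows are retained — they matter for presence/absence.
    """

    data: pd.DataFrame
    layer: str
    feature_kind: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing cells in rows {rows}; missing values are errors")
        if (df.to_numpy() < 0).any():
            r, c = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame) -> "CountTable":
        return CountTable(data=data, layer=self.layer, feature_kind=self.feature_kind)


@dataclass
class AnnotationMap:
    """Protein -> lineage / GO terms / length mappings.

    Proteins missing a taxon or GO mapping are kept and reported via
    :attr:`unannotated` rather than dropped.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    go_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, length in self.lengths.items():
            if length < 1:
                raise ValidationError(f"protein {pid!r}: length must be positive, got {length}")

    @property
    def protein_ids(self) -> set[str]:
        return set(self.lineages) | set(self.go_terms) | set(self.lengths)

    def unannotated(self) -> set[str]:
        """Proteins known to the map but missing a taxon or a GO assignment."""
        out = set()
        for pid in self.protein_ids:
            if not self.lineages.get(pid) or not self.go_terms.get(pid):
                out.add(pid)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)


def read_count_table(path: str | Path, layer: str, feature_kind: str) -> CountTable:
    """Parse a feature x sample TSV (first column feature id, header sample ids).

    Malformed numeric cells raise :class:`ParseError` naming the offending
    row and column; duplicate feature ids raise :class:`ValidationError`.
    """
    raw = _read_tsv(path)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature id(s): {dupes}")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            feature = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: malformed numeric cell at feature {feature!r}, sample {col!r}: "
                f"{raw.loc[feature, col]!r}"
            )
        numeric[col] = converted
    table = CountTable(data=numeric, layer=layer, feature_kind=feature_kind)
    assert len(table.features) == len(raw.index), "parser dropped rows"
    return table


#: Fixed leading columns of an Abacus-style protein table; the remaining
#: columns are per-run spectral counts.
PROTEIN_TABLE_COLUMNS = ("protein_id", "probability", "unique_peptides", "length")


def read_protein_table(
    path: str | Path, meta: Sequence[SampleMeta] | None = None
) -> list[ProteinRecord]:
    """Parse an Abacus-style protein TSV into :class:`ProteinRecord` objects.

    Run ids come from the header; if ``meta`` is given, every run column must
    match a metaproteome ``sample_id`` there.
    """
    raw = _read_tsv(path).reset_index()
    missing = [c for c in PROTEIN_TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    run_ids = [c for c in raw.columns if c not in PROTEIN_TABLE_COLUMNS]
    if not run_ids:
        raise ParseError(f"{path}: no spectral-count run columns found")
    if meta is not None:
        known = {m.sample_id for m in meta if m.layer == "metaproteome"}
        unmatched = [r for r in run_ids if r not in known]
        if unmatched:
            raise ValidationError(
                f"{path}: run id(s) not present in sample metadata: {unmatched}"
            )
    records = []
    for _, row in raw.iterrows():
        try:
            rec = ProteinRecord(
                protein_id=str(row["protein_id"]),
                length=int(row["length"]),
                probability=float(row["probability"]),
                unique_peptides=int(row["unique_peptides"]),
                spectral_counts={r: float(row[r]) for r in run_ids},
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(
                f"{path}: malformed row for protein {row['protein_id']!r}: {exc}"
            ) from exc
        records.append(rec)
    seen: set[str] = set()
    for rec in records:
        if rec.protein_id in seen:
            raise ValidationError(f"{path}: duplicate protein id {rec.protein_id!r}")
        seen.add(rec.protein_id)
    return records


def read_annotation_map(
    taxonomy_path: str | Path | None = None,
    go_path: str | Path | None = None,
    lengths_path: str | Path | None = None,
) -> AnnotationMap:
    """Merge two-column annotation TSVs into one :class:`AnnotationMap`.

    Taxonomy values are semicolon-delimited lineages ordered Kingdom -> Class;
    GO values are semicolon-delimited term ids (one row per protein, or
    several rows that are unioned).  Conflicting lengths for one protein are
    an error.
    """
    lineages: dict[str, tuple[str, ...]] = {}
    go_terms: dict[str, frozenset[str]] = {}
    lengths: dict[str, int] = {}
    if taxonomy_path is not None:
        df = pd.read_csv(taxonomy_path, sep="\t", comment="#", dtype=str)
        for pid, value in df.itertuples(index=False):
            lineage = tuple(r.strip() for r in str(value).split(";") if r.strip()) if pd.notna(value) else ()
            if pid in lineages and lineages[pid] != lineage:
                raise ValidationError(f"conflicting lineages for protein {pid!r}")
            lineages[pid] = lineage
    if go_path is not None:
        df = pd.read_csv(go_path, sep="\t", comment="#", dtype=str)
        for pid, value in df.itertuples(index=False):
            terms = frozenset(t.strip() for t in str(value).split(";") if t.strip()) if pd.notna(value) else frozenset()
            go_terms[pid] = go_terms.get(pid, frozenset()) | terms
    if lengths_path is not None:
        df = pd.read_csv(lengths_path, sep="\t", comment="#", dtype=str)
        for pid, value in df.itertuples(index=False):
            length = int(value)
            if pid in lengths and lengths[pid] != length:
                raise ValidationError(
                    f"conflicting lengths for protein {pid!r}: {lengths[pid]} vs {length}"
                )
            lengths[pid] = length
    # proteins seen in one file but absent from another get explicit empties
    all_ids = set(lineages) | set(go_terms) | set(lengths)
    for pid in all_ids:
        lineages.setdefault(pid, ())
        go_terms.setdefault(pid, frozenset())
    return AnnotationMap(lineages=lineages, go_terms=go_terms, lengths=lengths)


def read_sample_metadata(
    path: str | Path, day_order: Sequence[int] | None = None
) -> list[SampleMeta]:
    """Read sample metadata TSV with columns
    (sample_id, day, treatment, tank, layer, tech_replicate_group)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "day", "treatment", "tank", "layer"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {missing}")
    metas = []
    for _, row in df.iterrows():
        group = row.get("tech_replicate_group")
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                day=int(row["day"]),
                treatment=str(row["treatment"]),
                tank=str(row["tank"]),
                layer=str(row["layer"]),
                tech_replicate_group=None if pd.isna(group) else str(group),
            )
        )
    for layer in LAYERS:
        ids = [m.sample_id for m in metas if m.layer == layer]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"{path}: duplicate sample id(s) within layer {layer}: {dupes}")
    if day_order is not None:
        bad = sorted({m.day for m in metas} - set(day_order))
        if bad:
            raise ValidationError(f"{path}: day(s) {bad} not in configured day order {list(day_order)}")
    return metas


def read_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file (input paths, day order, thresholds, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.6g"


def write_table(result, path: str | Path, index_label: str | None = None) -> None:
    """Write any tabular result as TSV with deterministic column order.

    Accepts a :class:`CountTable`, a DataFrame, or a list of dataclass rows.
    Floats are rendered with 6 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, CountTable):
        result.data.to_csv(
            path, sep="\t", float_format=_FLOAT_FORMAT, index_label=index_label or "feature_id"
        )
        return
    if isinstance(result, pd.DataFrame):
        result.to_csv(
            path,
            sep="\t",
            float_format=_FLOAT_FORMAT,
            index=index_label is not None,
            index_label=index_label,
        )
        return
    if isinstance(result, (list, tuple)):
        import dataclasses

        if result and dataclasses.is_dataclass(result[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in result])
        else:
            df = pd.DataFrame(list(result))
        df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index=False)
        return
    raise TypeError(f"cannot write object of type {type(result).__name__}")


def write_sample_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "day": m.day,
                "treatment": m.treatment,
                "tank": m.tank,
                "layer": m.layer,
                "tech_replicate_group": m.tech_replicate_group or "",
            }
            for m in metas
        ]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_protein_table(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords back to the Abacus-style TSV schema."""
    if not records:
        raise ValidationError("cannot write an empty protein table")
    run_ids = list(records[0].spectral_counts)
    rows = []
    for rec in records:
        row = {
            "protein_id": rec.protein_id,
            "probability": rec.probability,
            "unique_peptides": rec.unique_peptides,
            "length": rec.length,
        }
        row.update({r: rec.spectral_counts[r] for r in run_ids})
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_annotation_map(ann: AnnotationMap, taxonomy_path: str | Path, go_path: str | Path) -> None:
    tax_rows = [
        {"protein_id": pid, "lineage": ";".join(ann.lineages.get(pid, ()))}
        for pid in sorted(ann.protein_ids)
    ]
    go_rows = [
        {"protein_id": pid, "go_terms": ";".join(sorted(ann.go_terms.get(pid, ())))}
        for pid in sorted(ann.protein_ids)
    ]
    pd.DataFrame(tax_rows).to_csv(taxonomy_path, sep="\t", index=False)
    pd.DataFrame(go_rows).to_csv(go_path, sep="\t", index=False)
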