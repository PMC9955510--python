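"""Tabular I/O and dataset-preparation transforms.

Expression matrices are genes x samples on a log2-intensity scale with Entrez
Gene row identifiers; radiomic feature tables are samples x features with
IBSI-style feature names. Readers validate and never transform values;
missing values are a hard error (no imputation is performed anywhere in the
pipeline).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FeatureTable",
    "ProbeGeneMap",
    "read_expression_table",
    "write_expression_table",
    "read_class_labels",
    "write_class_labels",
    "read_feature_table",
    "write_feature_table",
    "read_probe_gene_map",
    "collapse_probesets",
    "intersect_genes",
    "mean_center",
    "write_outputs",
]

SAMPLE_CLASSES = ("cancer", "normal", "unknown")
FEATURE_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

# text serialization keeps 17 significant digits so float64 round-trips exactly
FLOAT_FMT = "%.17g"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample class labels.

    gene_ids are Entrez Gene identifiers (strings); batch_id names the source
    dataset so per-dataset operations (mean-centering) have a defined boundary.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_class: list[str] = field(default_factory=list)
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if not self.sample_class:
            self.sample_class = ["unknown"] * len(self.sample_ids)
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(self.sample_class) != len(self.sample_ids):
            raise ValueError("sample_class length does not match sample_ids")
        bad = set(self.sample_class) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"invalid sample class labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[str(g)] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in matrix") from None

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx],
            list(self.sample_class),
            self.batch_id,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            [self.sample_class[i] for i in idx],
            self.batch_id,
        )

    def class_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.sample_class], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FeatureTable:
    """Samples x radiomic features (unitless values, IBSI-style names)."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_class: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if not self.feature_class:
            self.feature_class = [classify_feature(f) for f in self.feature_ids]
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.feature_ids, "feature ID")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        if len(self.feature_class) != len(self.feature_ids):
            raise ValueError("feature_class length does not match feature_ids")
        bad = set(self.feature_class) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"invalid feature class tags: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            s, f = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite feature value at sample {self.sample_ids[s]!r}, "
                f"feature {self.feature_ids[f]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, features) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[str(f)] for f in features]
        return FeatureTable(
            list(self.sample_ids),
            [self.feature_ids[i] for i in idx],
            self.values[:, idx],
            [self.feature_class[i] for i in idx],
        )

    def subset_samples(self, samples) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in samples]
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx],
            list(self.feature_class),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def classify_feature(name: str) -> str:
    """Map a filter_class_statistic feature name to its IBSI feature class.

    Names without a recognizable class token are tagged 'firstorder'.
    """
    tokens = name.lower().split("_")
    for cls in FEATURE_CLASSES:
        if cls in tokens:
            return cls
    return "firstorder"


@dataclass
class ProbeGeneMap:
    """Many-to-one probeset -> Entrez Gene mapping (unmapped probesets absent)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, probeset: str) -> str:
        return self.mapping[probeset]

    def __contains__(self, probeset: str) -> bool:
        return probeset in self.mapping


# ---------------------------------------------------------------------------
# readers / writers


def _read_numeric_table(path, sep: str, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate {index_name} {dup!r} in {path}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric or missing cell at row {row!r}, column {col!r} in {path}"
            )
        out[col] = converted.to_numpy()
    return out


def read_expression_table(path, class_map: dict | None = None, batch_id: str = "") -> ExpressionMatrix:
    """Read a tab-delimited genes x samples table (first column gene IDs)."""
    df = _read_numeric_table(path, "\t", "gene ID")
    samples = [str(c) for c in df.columns]
    classes = None
    if class_map is not None:
        class_map = {str(k): str(v) for k, v in class_map.items()}
        classes = [class_map.get(s, "unknown") for s in samples]
    return ExpressionMatrix(list(df.index), samples, df.to_numpy(), classes or [], batch_id)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_class_labels(path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>class -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"class-label file {path} must have exactly two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_class_labels(m: ExpressionMatrix, path) -> None:
    pd.DataFrame({"sample_id": m.sample_ids, "class": m.sample_class}).to_csv(
        path, sep="\t", index=False
    )


def read_feature_table(path) -> FeatureTable:
    """Read a comma-delimited samples x features table (first column sample IDs)."""
    df = _read_numeric_table(path, ",", "sample ID")
    return FeatureTable(list(df.index), [str(c) for c in df.columns], df.to_numpy())


def write_feature_table(t: FeatureTable, path) -> None:
    df = t.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, float_format=FLOAT_FMT)


def read_probe_gene_map(path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"probe map file {path} must have exactly two columns")
    return ProbeGeneMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# dataset-preparation transforms


def collapse_probesets(
    probe_matrix: ExpressionMatrix, probe_map: ProbeGeneMap
) -> tuple[ExpressionMatrix, int]:
    """Collapse a probeset-keyed matrix to one row per Entrez Gene.

    For genes covered by several probesets the retained row is the probeset
    with the largest mean expression across samples (a whole-probeset choice;
    per-sample maxima would mix rows from different probesets). Returns the
    collapsed matrix and the number of unmapped probesets dropped.
    """
    if len(probe_map) == 0:
        raise ValueError("probe-gene map is empty")
    best_row: dict[str, int] = {}
    best_mean: dict[str, float] = {}
    gene_order: list[str] = []
    dropped = 0
    means = probe_matrix.values.mean(axis=1)
    for i, probe in enumerate(probe_matrix.gene_ids):
        if probe not in probe_map:
            dropped += 1
            continue
        gene = probe_map[probe]
        if gene not in best_row:
            gene_order.append(gene)
            best_row[gene] = i
            best_mean[gene] = means[i]
        elif means[i] > best_mean[gene]:
            best_row[gene] = i
            best_mean[gene] = means[i]
    rows = [best_row[g] for g in gene_order]
    return (
        ExpressionMatrix(
            gene_order,
            list(probe_matrix.sample_ids),
            probe_matrix.values[rows],
            list(probe_matrix.sample_class),
            probe_matrix.batch_id,
        ),
        dropped,
    )


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common gene set, in a's gene order."""
    common_set = set(a.gene_ids) & set(b.gene_ids)
    if not common_set:
        raise ValueError("gene sets are disjoint: empty intersection")
    common = [g for g in a.gene_ids if g in common_set]
    return a.subset_genes(common), b.subset_genes(common)


def mean_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene mean-centering within the dataset (batch-effect control).

    The batch boundary is the matrix itself: each gene row ends up with mean
    exactly 0 across the samples present.
    """
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), centered, list(m.sample_class), m.batch_id
    )


# ---------------------------------------------------------------------------
# product serialization


def write_outputs(obj, path) -> list[str]:
    """Write any pipeline product into directory `path`; returns files written.

    Tables go out as TSV/CSV, model sets as one human-readable JSON document;
    every file round-trips through the matching reader.
    """
    # runtime imports keep io free of upward dependencies
    from . import meta_radiomics as mr
    from . import pmetaomics as pm
    from . import signature as sig

    os.makedirs(path, exist_ok=True)
    written: list[str] = []

    def _path(name: str) -> str:
        p = os.path.join(path, name)
        written.append(p)
        return p

    if isinstance(obj, ExpressionMatrix):
        write_expression_table(obj, _path("expression.tsv"))
        write_class_labels(obj, _path("classes.tsv"))
    elif isinstance(obj, FeatureTable):
        write_feature_table(obj, _path("features.csv"))
    elif isinstance(obj, mr.MetaRadiomicsSignature):
        obj.cluster_table().to_csv(_path("clusters.tsv"), sep="\t", index=False)
        write_feature_table(obj.meta_table(), _path("meta_features.csv"))
    elif isinstance(obj, sig.DegSet):
        obj.to_frame().to_csv(_path("degs.tsv"), sep="\t", index=False)
    elif isinstance(obj, sig.TranscriptomicSignature):
        obj.to_frame().to_csv(_path("signature.tsv"), sep="\t", index=False)
    elif isinstance(obj, pm.PMetaomicsSignature):
        with open(_path("pmetaomics_models.json"), "w") as fh:
            json.dump(obj.to_dict(), fh, indent=1)
        obj.diagnostics_table().to_csv(_path("pmetaomics_diagnostics.tsv"), sep="\t", index=False)
    elif dataclasses.is_dataclass(obj):
        with open(_path(type(obj).__name__.lower() + ".json"), "w") as fh:
            json.dump(dataclasses.asdict(obj), fh, indent=1, default=_json_default)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")
    return written


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)!r}")
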