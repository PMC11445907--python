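"""Data model and file I/O for multi-modal single-cell matrices.

The canonical in-memory orientation is cells x features everywhere
(``N x D_m`` for modality *m*).  Matrix Market files on disk follow the
10x convention (features x cells) and are transposed on load/write.
Dense CSV/TSV files carry a header row of feature ids and a first column
of cell ids, already in cells x features orientation.

The loader accepts any non-negative real matrix — raw counts or
normalized values alike — and records which it was handed (integral or
not) in :attr:`ModalityMatrix.is_integral`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "ModalityMatrix",
    "MultiModalDataset",
    "PipelineConfig",
    "load_modality",
    "load_labels",
    "assemble_dataset",
    "write_modality",
    "write_results",
    "load_config",
    "save_config",
]


@dataclass
class ModalityMatrix:
    """One measurement type (RNA, protein, ...) over N cells.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_features)
        Non-negative expression values.
    feature_ids, cell_ids : sequences of unique strings.
    name : human-readable modality name.
    """

    values: np.ndarray
    feature_ids: list
    cell_ids: list
    name: str = "modality"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"modality {self.name!r}: expected a 2-D matrix, got ndim={v.ndim}")
        n, d = v.shape
        if n < 2 or d < 2:
            raise ValueError(f"modality {self.name!r}: need at least 2 cells and 2 features, got {v.shape}")
        if len(self.cell_ids) != n:
            raise ValueError(
                f"modality {self.name!r}: {len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.feature_ids) != d:
            raise ValueError(
                f"modality {self.name!r}: {len(self.feature_ids)} feature ids for {d} columns"
            )
        if not np.all(np.isfinite(v)):
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(
                f"modality {self.name!r}: non-finite entry at cell {self.cell_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(
                f"modality {self.name!r}: negative entry {v[i, j]} at cell "
                f"{self.cell_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError(f"modality {self.name!r}: duplicate cell ids")
        if len(set(self.feature_ids)) != d:
            raise ValueError(f"modality {self.name!r}: duplicate feature ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_integral(self) -> bool:
        """True when every entry is a whole number (count-like input)."""
        return bool(np.all(self.values == np.round(self.values)))

    def reordered(self, cell_ids: Sequence[str]) -> "ModalityMatrix":
        """Return a copy with rows arranged to match ``cell_ids``."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            rows = [index[c] for c in cell_ids]
        except KeyError as exc:
            raise ValueError(f"modality {self.name!r}: missing cell id {exc.args[0]!r}")
        return ModalityMatrix(
            values=self.values[rows],
            feature_ids=list(self.feature_ids),
            cell_ids=[str(c) for c in cell_ids],
            name=self.name,
        )


@dataclass
class MultiModalDataset:
    """Aligned modalities over the same cells, plus optional ground truth."""

    modalities: list
    labels: Optional[np.ndarray] = None
    n_clusters: Optional[int] = None
    label_names: Optional[list] = None  # original class names, encoding order

    def __post_init__(self):
        if len(self.modalities) < 1:
            raise ValueError("need at least one modality")
        ref = self.modalities[0].cell_ids
        for m in self.modalities[1:]:
            if m.cell_ids != ref:
                raise ValueError(
                    f"modality {m.name!r} cell ids do not match the first modality"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(ref),):
                raise ValueError("labels length must equal the number of cells")
            k = int(self.labels.max()) + 1
            if self.labels.min() < 0 or set(np.unique(self.labels)) != set(range(k)):
                raise ValueError("labels must be encoded 0..K-1 with every class present")
            if self.n_clusters is None:
                self.n_clusters = k
            elif self.n_clusters < k:
                raise ValueError("n_clusters smaller than the number of label classes")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def cell_ids(self) -> list:
        return self.modalities[0].cell_ids

    def matrices(self) -> list:
        return [m.values for m in self.modalities]


@dataclass
class PipelineConfig:
    """Hyperparameters of the full recover-then-aggregate pipeline.

    Defaults follow the reference setting: encoder layers (512, 64) with a
    64-d bottleneck, 200 pretraining + 200 joint epochs at learning rate
    5e-4, recovery threshold 0.1, temperature 0.5.
    """

    n_clusters: int = 4
    threshold: float = 0.1
    rank: int = 50
    lambda1: float = 0.1
    lambda2: float = 0.1
    k_neighbors: int = 15
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    sim_update_every: int = 10
    encoder_dims: list = field(default_factory=lambda: [512, 64])
    bottleneck: int = 64
    epochs_pretrain: int = 200
    epochs_train: int = 200
    learning_rate: float = 5e-4
    temperature: float = 0.5
    balance: float = 1.0
    contrastive_mode: str = "self_exclude"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.rank < 1 or self.k_neighbors < 1 or self.n_clusters < 1:
            raise ValueError("rank, k_neighbors and n_clusters must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0 or self.balance < 0:
            raise ValueError("lambda1, lambda2 and balance must be non-negative")
        if self.temperature <= 0 or self.learning_rate <= 0:
            raise ValueError("temperature and learning_rate must be positive")
        if self.epochs_pretrain < 0 or self.epochs_train < 0:
            raise ValueError("epoch counts must be non-negative")
        self.encoder_dims = [int(d) for d in self.encoder_dims]
        if any(d < 1 for d in self.encoder_dims):
            raise ValueError("encoder_dims must be positive")
        if self.bottleneck != self.encoder_dims[-1]:
            raise ValueError("bottleneck must equal the last encoder dimension")
        if self.contrastive_mode not in ("self_exclude", "literal"):
            raise ValueError("contrastive_mode must be 'self_exclude' or 'literal'")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# loading


def _read_id_column(path: Path) -> list:
    """First column of a TSV, one id per line (10x features/barcodes files)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _load_mtx(path: Path, name: str) -> ModalityMatrix:
    if path.is_dir():
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        if not feat.exists():
            feat = path / "genes.tsv"
        bc = path / "barcodes.tsv"
    else:
        mtx = path
        feat = path.parent / "features.tsv"
        if not feat.exists():
            feat = path.parent / "genes.tsv"
        bc = path.parent / "barcodes.tsv"
    for p in (mtx, feat, bc):
        if not p.exists():
            raise FileNotFoundError(f"expected file {p} alongside the Matrix Market input")
    mat = scipy.io.mmread(str(mtx))
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    features = _read_id_column(feat)
    barcodes = _read_id_column(bc)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{mtx}: matrix is {mat.shape} but features.tsv has {len(features)} rows "
            f"and barcodes.tsv has {len(barcodes)} rows (expected features x cells)"
        )
    return ModalityMatrix(values=mat.T, feature_ids=features, cell_ids=barcodes, name=name)


def _load_dense(path: Path, sep: str, name: str) -> ModalityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ModalityMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=[str(c) for c in df.columns],
        cell_ids=[str(i) for i in df.index],
        name=name,
    )


def load_modality(path, fmt: Optional[str] = None, name: Optional[str] = None) -> ModalityMatrix:
    """Load one modality from ``mtx`` (10x triplet), ``csv`` or ``tsv``.

    ``fmt`` is inferred from the suffix when omitted; a directory implies
    the 10x ``matrix.mtx``/``features.tsv``/``barcodes.tsv`` triplet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt is None:
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        elif path.suffix in (".csv",):
            fmt = "csv"
        elif path.suffix in (".tsv", ".txt"):
            fmt = "tsv"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")
    name = name or path.stem
    if fmt == "mtx":
        return _load_mtx(path, name)
    if fmt == "csv":
        return _load_dense(path, ",", name)
    if fmt == "tsv":
        return _load_dense(path, "\t", name)
    raise ValueError(f"unknown format {fmt!r}")


def load_labels(path) -> pd.Series:
    """Read a two-column (cell_id, label) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (cell_id, label)")
    if list(df.iloc[0, :2]) == ["cell_id", "label"]:
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def assemble_dataset(
    modalities: Sequence[ModalityMatrix],
    labels_path=None,
    n_clusters: Optional[int] = None,
) -> MultiModalDataset:
    """Reconcile modalities on shared cells and attach optional labels.

    Cells are intersected across modalities and kept in the first
    modality's order; other modalities are row-reordered to match.
    String class labels are re-encoded to 0..K-1 by first appearance.
    """
    if len(modalities) < 1:
        raise ValueError("need at least one modality")
    common = set(modalities[0].cell_ids)
    for m in modalities[1:]:
        common &= set(m.cell_ids)
    if not common:
        raise ValueError("no cell ids shared across all modalities")
    order = [c for c in modalities[0].cell_ids if c in common]
    aligned = [m if m.cell_ids == order else m.reordered(order) for m in modalities]

    labels = None
    label_names = None
    if labels_path is not None:
        table = load_labels(labels_path)
        missing = [c for c in order if c not in table.index]
        if missing:
            raise ValueError(f"labels file lacks {len(missing)} cells, e.g. {missing[0]!r}")
        raw = [table.loc[c] for c in order]
        label_names = []
        code = {}
        labels = np.empty(len(raw), dtype=int)
        for i, r in enumerate(raw):
            if r not in code:
                code[r] = len(label_names)
                label_names.append(r)
            labels[i] = code[r]
    return MultiModalDataset(
        modalities=aligned, labels=labels, n_clusters=n_clusters, label_names=label_names
    )


# ---------------------------------------------------------------------------
# writing


def write_modality(outdir, modality: ModalityMatrix, stem: Optional[str] = None) -> dict:
    """Write one modality as a 10x-style mtx triplet; returns file records."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or modality.name
    sub = outdir / stem
    sub.mkdir(exist_ok=True)
    # disk convention is features x cells
    scipy.io.mmwrite(str(sub / "matrix.mtx"), sp.coo_matrix(modality.values.T))
    (sub / "features.tsv").write_text("\n".join(modality.feature_ids) + "\n")
    (sub / "barcodes.tsv").write_text("\n".join(modality.cell_ids) + "\n")
    return {
        "path": str(sub),
        "format": "mtx",
        "shape": [modality.n_cells, modality.n_features],
    }


def write_results(
    outdir,
    recovered: Sequence[ModalityMatrix],
    embedding: np.ndarray,
    labels: np.ndarray,
    metrics: Optional[dict] = None,
    label_names: Optional[list] = None,
) -> dict:
    """Persist pipeline outputs and return a manifest of what was written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for m in recovered:
        rec = write_modality(outdir, m, stem=f"recovered_{m.name}")
        rec["kind"] = "recovered_matrix"
        manifest["files"].append(rec)

    cell_ids = recovered[0].cell_ids if recovered else [str(i) for i in range(len(labels))]
    embedding = np.asarray(embedding)
    emb_path = outdir / "embedding.tsv"
    pd.DataFrame(embedding, index=cell_ids).to_csv(emb_path, sep="\t", header=False)
    manifest["files"].append(
        {"path": str(emb_path), "format": "tsv", "shape": list(embedding.shape), "kind": "embedding"}
    )

    labels = np.asarray(labels, dtype=int)
    lab_path = outdir / "labels.tsv"
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(
        lab_path, sep="\t", index=False
    )
    manifest["files"].append(
        {"path": str(lab_path), "format": "tsv", "shape": [len(labels)], "kind": "labels"}
    )

    if metrics is not None:
        met_path = outdir / "metrics.json"
        met_path.write_text(json.dumps(metrics, indent=2) + "\n")
        manifest["files"].append(
            {"path": str(met_path), "format": "json", "shape": [len(metrics)], "kind": "metrics"}
        )
    if label_names is not None:
        manifest["label_encoding"] = {str(i): str(n) for i, n in enumerate(label_names)}
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
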