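"""Readers and writers for the text formats the linker speaks.

Dense dialect: CSV/TSV with the patient id in the first column and one 0/1
column per code.  Sparse dialect: MatrixMarket (.mtx) with two sidecar
line-lists, ``<stem>.patient_ids.txt`` and ``<stem>.code_ids.txt``, one id
per line in matrix order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datasets import BinaryRecordDataset
from .matching import MatchSet, PosteriorMatrix
from .simulate import LinkedTruth

__all__ = [
    "read_binary_dataset",
    "write_binary_dataset",
    "read_truth_pairs",
    "write_match_table",
    "read_match_table",
    "write_posterior_mtx",
]


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (
        stem.parent / (stem.name + ".patient_ids.txt"),
        stem.parent / (stem.name + ".code_ids.txt"),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "mtx" if path.suffix == ".mtx" else "csv"


def read_binary_dataset(path, fmt: str | None = None) -> BinaryRecordDataset:
    """Load a patients × codes 0/1 matrix; rejects duplicates, ragged rows
    and non-binary cells, naming the offending location."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        pid_file, code_file = _sidecars(path)
        patient_ids = pid_file.read_text().split()
        code_ids = code_file.read_text().split()
        M = np.asarray(spio.mmread(path).todense())
        return BinaryRecordDataset(patient_ids, code_ids, M)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    patient_ids = [str(i) for i in df.index]
    code_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    M = np.zeros(values.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(values):
        if v not in ("0", "1"):
            raise ValueError(
                f"non-binary cell at patient {patient_ids[i]!r}, "
                f"code {code_ids[j]!r}: {v!r}"
            )
        M[i, j] = int(v)
    return BinaryRecordDataset(patient_ids, code_ids, M)


def write_binary_dataset(ds: BinaryRecordDataset, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        pid_file, code_file = _sidecars(path)
        pid_file.write_text("\n".join(ds.patient_ids) + "\n")
        code_file.write_text("\n".join(ds.code_ids) + "\n")
        spio.mmwrite(str(path), sparse.coo_matrix(ds.matrix))
        return
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    ds.to_frame().rename_axis("patient_id").to_csv(path, sep=sep)


def read_truth_pairs(path) -> LinkedTruth:
    """TSV of (patient_id_A, patient_id_B) true pairs, header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["patient_id_A", "patient_id_B"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return LinkedTruth(set(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_match_table(matches: MatchSet, path) -> None:
    rows = sorted(matches.pairs)
    df = pd.DataFrame(rows, columns=["patient_id_A", "patient_id_B", "posterior"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_match_table(path) -> MatchSet:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    pairs = {
        (str(a), str(b), float(s))
        for a, b, s in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    }
    return MatchSet(pairs, threshold_used=float("nan"))


def write_posterior_mtx(post: PosteriorMatrix, path, cutoff: float = 1e-6) -> None:
    """Sparse posterior matrix (entries below ``cutoff`` dropped) with id
    sidecars, for downstream weighted analyses."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pid_file, code_file = _sidecars(path)
    pid_file.write_text("\n".join(post.patient_ids_A) + "\n")
    code_file.write_text("\n".join(post.patient_ids_B) + "\n")
    P = np.where(post.probs >= cutoff, post.probs, 0.0)
    spio.mmwrite(str(path), sparse.coo_matrix(P))
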