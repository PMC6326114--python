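"""Patient-by-code binary datasets and code alignment.

A record here is a patient's vector of ever-present / never-present
indicators over a set of diagnosis codes (e.g. binarized ICD-9 codes).
Two datasets to be linked rarely share an identical code dictionary, so
linkage operates on an explicit :class:`CodeAlignment` — the union (default)
or intersection of the two code sets, in deterministic lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryRecordDataset",
    "CodeAlignment",
    "align_codes",
    "filter_rare_codes",
]


@dataclass
class BinaryRecordDataset:
    """One dataset's patients × codes presence/absence matrix.

    Parameters
    ----------
    patient_ids
        Unique opaque identifiers, one per row.
    code_ids
        Unique code labels, one per column.
    matrix
        ``(n_patients, n_codes)`` array of 0/1 indicators; 1 means the code
        was recorded at least once for that patient.
    """

    patient_ids: Sequence[str]
    code_ids: Sequence[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = list(map(str, self.patient_ids))
        self.code_ids = list(map(str, self.code_ids))
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        n, k = self.matrix.shape
        if n != len(self.patient_ids) or k != len(self.code_ids):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.code_ids)} codes"
            )
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient identifiers")
        if len(set(self.code_ids)) != k:
            raise ValueError("duplicate code identifiers")
        bad = ~np.isin(self.matrix, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at patient {self.patient_ids[i]!r}, "
                f"code {self.code_ids[j]!r}: {self.matrix[i, j]!r}"
            )
        self.matrix = self.matrix.astype(np.int8, copy=False)

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_codes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.patient_ids, columns=self.code_ids)

    def reindexed(self, code_ids: Sequence[str]) -> np.ndarray:
        """Matrix re-ordered onto ``code_ids``; codes absent here become
        all-zero columns (a code never recorded is indistinguishable from a
        code not collected, which is exactly the union-policy semantics)."""
        out = np.zeros((self.n_patients, len(code_ids)), dtype=np.int8)
        pos = {c: j for j, c in enumerate(self.code_ids)}
        for j, c in enumerate(code_ids):
            if c in pos:
                out[:, j] = self.matrix[:, pos[c]]
        return out


@dataclass
class CodeAlignment:
    """Shared code order used for linkage between two datasets."""

    shared_code_ids: list[str]
    index_in_A: list[int | None]
    index_in_B: list[int | None]
    policy: str

    def __post_init__(self) -> None:
        if self.policy not in ("union", "intersection"):
            raise ValueError(f"unknown alignment policy {self.policy!r}")
        if len(self.shared_code_ids) < 1:
            raise ValueError("alignment must contain at least one code")
        if len(set(self.shared_code_ids)) != len(self.shared_code_ids):
            raise ValueError("duplicate codes in alignment")
        if self.policy == "intersection" and (
            any(i is None for i in self.index_in_A)
            or any(i is None for i in self.index_in_B)
        ):
            raise ValueError("intersection alignment cannot contain absent codes")

    @property
    def n_codes(self) -> int:
        return len(self.shared_code_ids)


def align_codes(
    A: BinaryRecordDataset, B: BinaryRecordDataset, policy: str = "union"
) -> CodeAlignment:
    """Build the shared code order (lexicographic) under ``union`` or
    ``intersection`` policy."""
    codes_a, codes_b = set(A.code_ids), set(B.code_ids)
    if policy == "union":
        shared = sorted(codes_a | codes_b)
    elif policy == "intersection":
        shared = sorted(codes_a & codes_b)
        if not shared:
            raise ValueError("datasets share no codes under intersection policy")
    else:
        raise ValueError(f"unknown alignment policy {policy!r}")
    pos_a = {c: j for j, c in enumerate(A.code_ids)}
    pos_b = {c: j for j, c in enumerate(B.code_ids)}
    return CodeAlignment(
        shared_code_ids=shared,
        index_in_A=[pos_a.get(c) for c in shared],
        index_in_B=[pos_b.get(c) for c in shared],
        policy=policy,
    )


def filter_rare_codes(
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    align: CodeAlignment,
    min_count: int = 1,
) -> CodeAlignment:
    """Drop codes recorded fewer than ``min_count`` times in the pooled data.

    Extremely rare codes can dominate the likelihood; the default
    ``min_count=1`` only removes codes never recorded in either dataset.
    """
    MA = A.reindexed(align.shared_code_ids)
    MB = B.reindexed(align.shared_code_ids)
    pooled = MA.sum(axis=0) + MB.sum(axis=0)
    keep = pooled >= min_count
    if not keep.any():
        raise ValueError("rare-code filter removed every code")
    kept_codes = [c for c, k in zip(align.shared_code_ids, keep) if k]
    return CodeAlignment(
        shared_code_ids=kept_codes,
        index_in_A=[i for i, k in zip(align.index_in_A, keep) if k],
        index_in_B=[i for i, k in zip(align.index_in_B, keep) if k],
        policy=align.policy,
    )
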