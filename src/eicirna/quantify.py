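"""Cross-sample quantification: BRPM, expression matrices and tau.

BRPM (back-spliced reads per million) depth-normalizes a BSJ count by
the library's total mapped reads. The tissue-specificity index tau
(Yanai-style) maps a per-tissue expression vector to [0, 1]:
0 for uniform expression, 1 for single-tissue expression.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .retention import EIciRNARecord


def brpm(bsj_count: int, total_mapped_reads: int) -> float:
    """bsj_count / total_mapped_reads * 1e6."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if bsj_count < 0:
        raise ValueError("negative BSJ count")
    return bsj_count / total_mapped_reads * 1e6


@dataclass
class TauResult:
    feature_id: str
    tau: float | None
    n_tissues: int
    max_tissue: str | None

    @property
    def defined(self) -> bool:
        return self.tau is not None


def tau(
    values: Sequence[float],
    tissues: Sequence[str] | None = None,
    log_transform: bool = True,
    feature_id: str = "",
) -> TauResult:
    """tau = sum_i(1 - x_i / x_max) / (n - 1) over per-tissue values.

    Values are log2(x + 1)-transformed first by default (common
    practice for expression-based tau; switch off with
    ``log_transform=False``). All-zero vectors are flagged undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression values")
    names = list(tissues) if tissues is not None else [str(i) for i in range(x.size)]
    if x.max() == 0:
        return TauResult(feature_id, None, x.size, None)
    if log_transform:
        x = np.log2(x + 1.0)
    t = float(np.sum(1.0 - x / x.max()) / (x.size - 1))
    return TauResult(feature_id, t, x.size, names[int(np.argmax(x))])


class ExpressionMatrix:
    """Features x samples of non-negative expression, with tissue labels."""

    def __init__(self, data: pd.DataFrame, tissue_of: Mapping[str, str] | None = None):
        if (data.values < 0).any():
            raise ValueError("negative expression values")
        if data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = data
        self.tissue_of = dict(tissue_of or {s: s for s in data.columns})

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def by_tissue(self) -> pd.DataFrame:
        """Average replicate samples within each tissue (arithmetic mean)."""
        groups = pd.Series({s: self.tissue_of.get(s, s) for s in self.data.columns})
        return self.data.T.groupby(groups).mean().T

    def tau_table(self, log_transform: bool = True) -> list[TauResult]:
        per_tissue = self.by_tissue()
        return [
            tau(per_tissue.loc[fid].values, list(per_tissue.columns),
                log_transform=log_transform, feature_id=str(fid))
            for fid in per_tissue.index
        ]


def _feature_key(record: EIciRNARecord) -> str:
    iv = record.interval
    introns = ";".join(
        f"{i.interval.start}-{i.interval.end}" for i in record.introns
    )
    return f"{iv.contig}:{iv.start}-{iv.end}|{introns}"


def build_matrix(
    per_sample_records: Mapping[str, list[EIciRNARecord]],
    tissue_of: Mapping[str, str] | None = None,
    value: str = "brpm",
) -> ExpressionMatrix:
    """Assemble a features x samples matrix from per-sample records.

    Features are keyed by (BSJ span, retained intron set); records
    absent from a sample get 0. ``value`` selects BRPM (requires
    records quantified) or the raw BSJ count.
    """
    samples = list(per_sample_records)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    rows: dict[str, dict[str, float]] = {}
    for sample, records in per_sample_records.items():
        for r in records:
            key = _feature_key(r)
            if value == "brpm":
                if r.brpm is None:
                    raise ValueError(f"record {r.circ_id} has no BRPM")
                v = r.brpm
            else:
                v = float(r.bsj_count)
            rows.setdefault(key, {})[sample] = v
    data = pd.DataFrame(
        [[rows.get(f, {}).get(s, 0.0) for s in samples] for f in rows],
        index=list(rows), columns=samples, dtype=float,
    )
    if data.empty:
        data = pd.DataFrame(np.zeros((0, len(samples))), columns=samples)
    return ExpressionMatrix(data, tissue_of)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, value: str = "BRPM") -> None:
    with open(path, "w") as fh:
        fh.write(f"# value: {value}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id")


def write_tau(results: list[TauResult], path: str | Path, log_transform: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# transform: {'log2(x+1)' if log_transform else 'none'}\n")
        fh.write("feature_id\ttau\tn_tissues\tmax_tissue\n")
        for r in results:
            t = f"{r.tau:.6f}" if r.tau is not None else "NA"
            fh.write(f"{r.feature_id}\t{t}\t{r.n_tissues}\t{r.max_tissue or 'NA'}\n")
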