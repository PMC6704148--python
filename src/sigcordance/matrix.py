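"""Gene-by-sample expression matrix container.

Expression values are log2(FPKM + offset); the offset keeps zero-FPKM
measurements finite. The container is a thin, validated wrapper around a
``pandas.DataFrame`` (rows = genes, columns = samples) so that every
downstream stage can rely on unique identifiers and finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_LOG_OFFSET = 0.1


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order; unknown genes error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def shared_genes(self, genes) -> list[str]:
        present = set(self.gene_ids)
        return [g for g in genes if g in present]

    def sample_vector(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)

    def write_tsv(self, path, float_format: str = "%.6g") -> None:
        """Write as TSV: first column gene id, header row = sample ids."""
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t", float_format=float_format)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls.from_frame(frame)
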