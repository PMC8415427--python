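"""Dense gene-by-sample expression container with TSV and MatrixMarket I/O.

Values are non-negative measurements on any scale whose within-sample
ranking is meaningful (counts, TPM, microarray intensities).  NaN marks a
missing measurement for a single (gene, sample) pair; downstream rank
tests drop such entries pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with string identifiers on both axes."""

    values: np.ndarray
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.genes), list(sample_ids))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), list(self.samples))

    # --- plain-text I/O -------------------------------------------------

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="gene")
        return path

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)

    def to_mtx(self, prefix) -> Path:
        """Write MatrixMarket triplets plus row/column name sidecars.

        Creates ``<prefix>.mtx``, ``<prefix>.rows.txt`` and
        ``<prefix>.cols.txt``.
        """
        prefix = Path(prefix)
        spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(self.values))
        prefix.with_suffix(".rows.txt").write_text("\n".join(self.genes) + "\n")
        prefix.with_suffix(".cols.txt").write_text("\n".join(self.samples) + "\n")
        return prefix.with_suffix(".mtx")

    @classmethod
    def from_mtx(cls, prefix) -> "ExpressionMatrix":
        prefix = Path(prefix)
        values = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
        genes = prefix.with_suffix(".rows.txt").read_text().splitlines()
        samples = prefix.with_suffix(".cols.txt").read_text().splitlines()
        return cls(values, genes, samples)
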