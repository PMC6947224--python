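"""Bundled reference dataset.

``conceptus_y_cpm.tsv`` holds the published per-gene CPM values of the ten
informative Y-chromosome genes for 35 pig conceptuses (17 genetic males,
18 genetic females; embryos at 25 days and fetuses at 35 days of
gestation), together with the published per-sample ΣCPM_chrY column.  The
sample identifier suffix (-M / -F) encodes the sex call of record.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import ChromosomeMap, CpmMatrix

#: The ten informative Y-chromosome genes, in published order.
Y_GENES = (
    "DDX3Y",
    "KDM5D",
    "ZFY",
    "EIF2S3Y",
    "EIF1AY",
    "LOC110255320",
    "LOC110257894",
    "LOC396706",
    "LOC100625207",
    "LOC110255257",
)


def _fixture_frame() -> pd.DataFrame:
    with resources.files("sexcpm.data").joinpath("conceptus_y_cpm.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="sample_id")


def load_conceptus_cpm() -> tuple[CpmMatrix, pd.Series, pd.Series]:
    """Load the reference dataset.

    Returns
    -------
    cpm : CpmMatrix
        10 genes × 35 samples, genes in published order (no library sizes —
        these are pre-computed CPM values).
    published_sigma : pd.Series
        The published per-sample ΣCPM_chrY, indexed by sample_id.
    labels : pd.Series
        'male' / 'female' per sample, from the sample-id suffix.
    """
    df = _fixture_frame()
    cpm = CpmMatrix(df[list(Y_GENES)].T)
    published_sigma = df["sigma_cpm_published"].rename("sigma_cpm")
    labels = pd.Series(
        ["male" if sid.endswith("-M") else "female" for sid in df.index],
        index=df.index,
        name="label",
    )
    return cpm, published_sigma, labels


def conceptus_chrom_map() -> ChromosomeMap:
    """Chromosome map placing the ten reference genes on Y."""
    return ChromosomeMap.from_pairs((g, "Y") for g in Y_GENES)
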