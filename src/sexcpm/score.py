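"""The sex-scoring computation.

The pipeline: normalize gene-level counts to counts-per-million (CPM),
find Y-chromosome genes whose per-sample CPM values are *discrepant* — a
clearly separated low group (genetic females, residual X/Y mismapping
reads only) and high group (genetic males) — sum the CPM of those genes
per sample (ΣCPM_chrY), and call sex by thresholding that sum.

The discrepancy criterion formalizes "high and low CPM values" as
largest-gap bimodality: sort a gene's per-sample CPM, split at the widest
consecutive gap, and require (a) both groups of at least ``min_group``
samples, (b) a high-group minimum of at least ``min_high_cpm``, and (c) a
high/low separation of at least ``min_fold`` (with the low maximum floored
at ``GAP_EPSILON`` CPM so all-zero female rows do not divide by zero).

Defaults are calibrated against the reference conceptus dataset: the
weakest of its ten informative genes separates ~67-fold (KDM5D, high
minimum 5.35 CPM vs low maximum 0.08 CPM) and the faintest male band
bottoms out at 1.23 CPM, so min_fold=20 and min_high_cpm=0.5 accept all
ten with margin for counting noise while rejecting artifact-level genes,
which never approach 0.5 CPM in a coherent high group.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ChromosomeMap,
    ConsistencyError,
    CountsMatrix,
    CpmMatrix,
    GeneSelection,
    GroupSummary,
    SexCallTable,
    normalize_chrom,
)

#: Floor for the low-group maximum in the separation ratio (CPM units).
GAP_EPSILON = 0.01

#: Minimum high/low separation ratio for a discrepant gene.
DEFAULT_MIN_FOLD = 20.0
#: Minimum CPM the high group must reach (rejects artifact-only genes).
DEFAULT_MIN_HIGH_CPM = 0.5

#: ΣCPM_chrY above which a sample is called male (strict inequality).
DEFAULT_MALE_THRESHOLD = 400.0
#: ΣCPM_chrY below which a sample is called female (strict inequality).
DEFAULT_FEMALE_THRESHOLD = 2.0


def compute_cpm(counts: CountsMatrix, include_summary_in_library: bool = False) -> CpmMatrix:
    """Counts-per-million normalization.

    The library size of a sample is its column sum over retained genes;
    ``include_summary_in_library=True`` additionally counts the stripped
    ``__``-prefixed totals in the denominator.

    Raises
    ------
    ConsistencyError
        If any sample has a zero library size.
    """
    lib = counts.counts.sum(axis=0)
    if include_summary_in_library and counts.summary is not None:
        lib = lib + counts.summary.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ConsistencyError(f"zero library size for sample(s) {zero}")
    cpm = counts.counts / lib * 1e6
    return CpmMatrix(cpm, library_sizes=lib.astype(np.int64))


def _largest_gap_split(values: np.ndarray) -> tuple[int, float]:
    """Index i and width of the largest gap between sorted values.

    The low group is ``sorted[:i+1]``, the high group ``sorted[i+1:]``.
    Ties break toward the lowest index (stable).
    """
    gaps = np.diff(values)
    i = int(np.argmax(gaps))
    return i, float(gaps[i])


def select_informative_genes(
    cpm: CpmMatrix,
    chrom_map: ChromosomeMap,
    target_chrom: str = "Y",
    min_fold: float = DEFAULT_MIN_FOLD,
    min_high_cpm: float = DEFAULT_MIN_HIGH_CPM,
    min_group: int = 2,
) -> GeneSelection:
    """Select target-chromosome genes with bimodal (discrepant) CPM.

    Candidate genes are those present in ``cpm`` that the map places on
    ``target_chrom``; they are evaluated and returned in input gene order.
    """
    if cpm.cpm.shape[1] < 2 * min_group:
        raise ConsistencyError(
            f"need at least {2 * min_group} samples, got {cpm.cpm.shape[1]}"
        )
    target = normalize_chrom(target_chrom)
    candidates = [g for g in cpm.gene_ids if g in chrom_map and chrom_map.chromosome(g) == target]
    if not candidates:
        raise ConsistencyError(f"no genes on chromosome {target!r} in the map")

    records = []
    selected: list[str] = []
    n = cpm.cpm.shape[1]
    for gene in candidates:
        values = np.sort(cpm.cpm.loc[gene].to_numpy(dtype=float))
        i, gap = _largest_gap_split(values)
        low_max = values[i]
        high_min = values[i + 1]
        n_low, n_high = i + 1, n - (i + 1)
        ratio = high_min / max(low_max, GAP_EPSILON)
        ok = (
            min(n_low, n_high) >= min_group
            and high_min >= min_high_cpm
            and ratio >= min_fold
        )
        if ok:
            selected.append(gene)
        records.append(
            dict(
                gene_id=gene,
                selected=ok,
                low_max=low_max,
                high_min=high_min,
                ratio=ratio,
                n_low=n_low,
                n_high=n_high,
            )
        )
    diagnostics = pd.DataFrame.from_records(records).set_index("gene_id")
    return GeneSelection(selected_gene_ids=selected, diagnostics=diagnostics)


def sigma_cpm(cpm: CpmMatrix, genes: list[str]) -> pd.Series:
    """Per-sample sum of CPM over ``genes`` (ΣCPM_chrY), in sample order."""
    missing = [g for g in genes if g not in cpm.cpm.index]
    if missing:
        raise ConsistencyError(f"gene_id(s) not in CPM matrix: {missing}")
    if not genes:
        return pd.Series(0.0, index=cpm.cpm.columns, name="sigma_cpm")
    return cpm.cpm.loc[list(genes)].sum(axis=0).rename("sigma_cpm")


def classify(
    sigma: pd.Series,
    male_threshold: float = DEFAULT_MALE_THRESHOLD,
    female_threshold: float = DEFAULT_FEMALE_THRESHOLD,
    n_genes_used: int | None = None,
) -> SexCallTable:
    """Threshold ΣCPM_chrY into male / female / undetermined calls.

    Both comparisons are strict: sigma strictly above ``male_threshold`` is
    male, strictly below ``female_threshold`` is female, anything in the
    closed gap between them is undetermined.
    """
    if not female_threshold < male_threshold:
        raise ValueError(
            f"female_threshold ({female_threshold}) must be below "
            f"male_threshold ({male_threshold})"
        )
    labels = np.where(
        sigma.to_numpy() > male_threshold,
        "male",
        np.where(sigma.to_numpy() < female_threshold, "female", "undetermined"),
    )
    table = pd.DataFrame(
        {
            "sample_id": sigma.index.astype(str),
            "sigma_cpm": sigma.to_numpy(dtype=float),
            "label": labels,
            "n_genes_used": 0 if n_genes_used is None else int(n_genes_used),
        }
    )
    return SexCallTable(table)


def summarize_groups(calls: SexCallTable) -> list[GroupSummary]:
    """n / mean / sample SD (n−1) / min / max of ΣCPM_chrY per label.

    Labels with no members are absent; SD is ``None`` for singleton groups.
    Values are reported at full precision; round at the output boundary.
    """
    out: list[GroupSummary] = []
    for label in ("male", "female", "undetermined"):
        values = calls.table.loc[calls.table["label"] == label, "sigma_cpm"]
        if values.empty:
            continue
        out.append(
            GroupSummary(
                label=label,
                n=int(values.size),
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)) if values.size >= 2 else None,
                min=float(values.min()),
                max=float(values.max()),
            )
        )
    return out


def run_pipeline(
    cpm: CpmMatrix,
    chrom_map: ChromosomeMap,
    genes: list[str] | None = None,
    target_chrom: str = "Y",
    male_threshold: float = DEFAULT_MALE_THRESHOLD,
    female_threshold: float = DEFAULT_FEMALE_THRESHOLD,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_high_cpm: float = DEFAULT_MIN_HIGH_CPM,
    min_group: int = 2,
) -> tuple[SexCallTable, GeneSelection | None]:
    """Selection (unless ``genes`` is given) → ΣCPM → classification."""
    selection = None
    if genes is None:
        selection = select_informative_genes(
            cpm, chrom_map, target_chrom, min_fold, min_high_cpm, min_group
        )
        genes = selection.selected_gene_ids
    sigma = sigma_cpm(cpm, genes)
    calls = classify(sigma, male_threshold, female_threshold, n_genes_used=len(genes))
    return calls, selection
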