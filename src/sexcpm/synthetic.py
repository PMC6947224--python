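"""Synthetic sexed RNA-seq count matrices.

The generator emulates the count-level structure the sex-scoring pipeline
assumes:

* per-sample library sizes around ~13 million counted reads;
* an autosomal background of overdispersed (gamma-Poisson, i.e. negative
  binomial) counts over log-normal gene means — its only role is a
  realistic CPM denominator;
* a panel of Y-chromosome genes, of which ``n_informative`` are truly
  male-expressed: male samples receive counts targeting a CPM drawn
  uniformly inside a per-gene band, while female samples receive sparse
  Poisson "mismapping artifact" counts at a CPM-scale rate — mimicking
  short reads from X/Y-homologous regions mis-assigned to Y;
* the remaining Y genes carry artifact-level counts in every sample.

Randomness is counter-keyed: each gene owns a child ``SeedSequence`` of the
global seed (library sizes have a per-sample substream), so enlarging the
gene panel never perturbs counts already generated for existing genes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import datasets
from .types import ChromosomeMap, CountsMatrix

_STREAM_LIB = 0
_STREAM_AUTOSOME = 1
_STREAM_CHRY = 2

#: Default per-gene female artifact rate (CPM). Calibrated to the reference
#: dataset, whose female group mean ΣCPM of 0.38 over ten genes implies
#: ~0.04 CPM of mismapped reads per gene.
DEFAULT_ARTIFACT_CPM = 0.04


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``male_cpm_bands`` (one (low, high) CPM pair per informative gene) and
    ``artifact_cpm`` (per-informative-gene female rate) default to values
    derived from the bundled reference dataset when ``n_informative`` is 10;
    otherwise they must be supplied.
    """

    n_male: int
    n_female: int
    seed: int
    n_autosomal_genes: int = 20_000
    n_chry_genes: int = 79
    n_informative: int = 10
    library_size_mean: float = 13_000_000.0
    library_size_cv: float = 0.1
    male_cpm_bands: tuple[tuple[float, float], ...] | None = None
    artifact_cpm: tuple[float, ...] | None = None
    noise_gene_cpm: float = 0.02
    autosomal_log_sd: float = 1.5
    autosomal_dispersion: float = 0.1
    min_separation_fold: float = 100.0
    informative_gene_ids: tuple[str, ...] | None = None

    def resolved(self) -> "SimConfig":
        """Fill band/rate defaults and validate feasibility."""
        cfg = self
        if cfg.male_cpm_bands is None or cfg.artifact_cpm is None:
            bands, rates = _reference_bands_and_rates()
            if cfg.n_informative != len(bands):
                raise ValueError(
                    "male_cpm_bands/artifact_cpm must be supplied when "
                    f"n_informative != {len(bands)}"
                )
            cfg = replace(
                cfg,
                male_cpm_bands=cfg.male_cpm_bands or bands,
                artifact_cpm=cfg.artifact_cpm or rates,
            )
        _validate(cfg)
        return cfg


def _validate(cfg: SimConfig) -> None:
    if cfg.n_male < 0 or cfg.n_female < 0 or cfg.n_male + cfg.n_female == 0:
        raise ValueError("need a non-empty sample set")
    if cfg.n_informative > cfg.n_chry_genes:
        raise ValueError("n_informative exceeds n_chry_genes")
    if len(cfg.male_cpm_bands) != cfg.n_informative:
        raise ValueError("one CPM band per informative gene required")
    if len(cfg.artifact_cpm) != cfg.n_informative:
        raise ValueError("one artifact rate per informative gene required")
    if cfg.library_size_mean <= 0 or cfg.library_size_cv < 0:
        raise ValueError("invalid library-size parameters")
    for (low, high), rate in zip(cfg.male_cpm_bands, cfg.artifact_cpm):
        if not 0 < low <= high:
            raise ValueError(f"invalid CPM band ({low}, {high})")
        if rate < 0:
            raise ValueError("negative artifact rate")
        if low / max(rate, 0.01) < cfg.min_separation_fold:
            raise ValueError(
                f"band lower bound {low} within {cfg.min_separation_fold}-fold "
                f"of artifact rate {rate}: males and females would not separate"
            )


def _reference_bands_and_rates() -> tuple[tuple[tuple[float, float], ...], tuple[float, ...]]:
    cpm, _, labels = datasets.load_conceptus_cpm()
    males = cpm.cpm.loc[:, labels == "male"]
    females = cpm.cpm.loc[:, labels == "female"]
    bands = tuple((float(r.min()), float(r.max())) for _, r in males.iterrows())
    rates = tuple(float(r.mean()) for _, r in females.iterrows())
    return bands, rates


def reference_config(seed: int, **overrides) -> SimConfig:
    """The study-scale configuration: 17 males, 18 females, 79 Y genes of
    which 10 are informative, with per-gene male CPM bands and female
    artifact rates taken from the bundled reference dataset."""
    cfg = SimConfig(
        n_male=17,
        n_female=18,
        seed=seed,
        informative_gene_ids=datasets.Y_GENES,
        **overrides,
    )
    return cfg.resolved()


@dataclass
class SyntheticTruth:
    """A generated dataset with its ground truth."""

    counts: CountsMatrix
    chrom_map: ChromosomeMap
    true_labels: pd.Series  # sample_id -> 'male' | 'female'
    true_informative_genes: list[str]
    config: SimConfig


def _rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def generate_dataset(config: SimConfig) -> SyntheticTruth:
    """Draw one synthetic CountsMatrix plus ground truth. Deterministic in the seed."""
    cfg = config.resolved()
    n = cfg.n_male + cfg.n_female
    sample_ids = [f"M{i + 1:02d}" for i in range(cfg.n_male)] + [
        f"F{i + 1:02d}" for i in range(cfg.n_female)
    ]
    is_male = np.array([True] * cfg.n_male + [False] * cfg.n_female)

    lib = np.array(
        [
            _rng(cfg.seed, _STREAM_LIB, i).lognormal(
                np.log(cfg.library_size_mean)
                - 0.5 * np.log1p(cfg.library_size_cv**2),
                np.sqrt(np.log1p(cfg.library_size_cv**2)),
            )
            for i in range(n)
        ]
    )

    # Autosomal background: per-gene log-normal mean count, gamma-Poisson draws.
    mean_count = cfg.library_size_mean / max(cfg.n_autosomal_genes, 1)
    mu_log = np.log(mean_count) - 0.5 * cfg.autosomal_log_sd**2
    scale = lib / cfg.library_size_mean
    auto = np.empty((cfg.n_autosomal_genes, n), dtype=np.int64)
    inv_disp = 1.0 / cfg.autosomal_dispersion
    for g in range(cfg.n_autosomal_genes):
        rng = _rng(cfg.seed, _STREAM_AUTOSOME, g)
        m = rng.lognormal(mu_log, cfg.autosomal_log_sd) * scale
        lam = rng.gamma(inv_disp, m * cfg.autosomal_dispersion)
        auto[g] = rng.poisson(lam)

    # Y-chromosome panel: informative genes first, then artifact-only genes.
    if cfg.informative_gene_ids is not None:
        inf_ids = list(cfg.informative_gene_ids)
        if len(inf_ids) != cfg.n_informative:
            raise ValueError("informative_gene_ids length must equal n_informative")
    else:
        inf_ids = [f"chrY_inf{i + 1:02d}" for i in range(cfg.n_informative)]
    noise_ids = [f"chrY_art{i + 1:02d}" for i in range(cfg.n_chry_genes - cfg.n_informative)]

    chry = np.empty((cfg.n_chry_genes, n), dtype=np.int64)
    for g in range(cfg.n_informative):
        rng = _rng(cfg.seed, _STREAM_CHRY, g)
        low, high = cfg.male_cpm_bands[g]
        # The band is a realized CPM range (it already contains counting
        # noise), so male counts hit the drawn target directly; only the
        # sparse female artifact reads are Poisson.
        male_counts = np.rint(rng.uniform(low, high, size=n) * lib / 1e6)
        female_counts = rng.poisson(cfg.artifact_cpm[g] * lib / 1e6)
        chry[g] = np.where(is_male, male_counts, female_counts).astype(np.int64)
    for g in range(cfg.n_informative, cfg.n_chry_genes):
        rng = _rng(cfg.seed, _STREAM_CHRY, g)
        chry[g] = rng.poisson(cfg.noise_gene_cpm * lib / 1e6)

    auto_ids = [f"gene{g + 1:05d}" for g in range(cfg.n_autosomal_genes)]
    counts = pd.DataFrame(
        np.vstack([auto, chry]),
        index=pd.Index(auto_ids + inf_ids + noise_ids, name="gene_id"),
        columns=sample_ids,
    )
    chrom_pairs = [(g, str(1 + i % 18)) for i, g in enumerate(auto_ids)]
    chrom_pairs += [(g, "Y") for g in inf_ids + noise_ids]

    return SyntheticTruth(
        counts=CountsMatrix(counts),
        chrom_map=ChromosomeMap.from_pairs(chrom_pairs),
        true_labels=pd.Series(
            np.where(is_male, "male", "female"), index=sample_ids, name="label"
        ),
        true_informative_genes=inf_ids,
        config=cfg,
    )
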