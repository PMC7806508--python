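"""Synthetic thyroid-carcinoma cohorts with known ground truth.

Generates negative-binomial RNA-seq count matrices with class structure
(ATC / PTC / FTC / PDTC / NT), spiked ATC-exclusive "de novo" marker genes
and decoys, plus immunohistochemistry cohort tables and gene-set
collections, so that every downstream stage (normalization, differential
expression, marker screen, GSEA, diagnostics) can be exercised against a
known truth table without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_CLASSES = ("ATC", "PTC", "FTC", "PDTC", "NT")

#: gene roles recorded in the truth table
ROLE_SPIKED = "spiked_marker"
ROLE_DECOY_HIGH_RSD = "decoy_high_rsd"
ROLE_DECOY_EXPRESSED = "decoy_expressed"
ROLE_BACKGROUND = "background"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RNA-seq cohort.

    Counts are drawn per gene g and sample s as NB with mean
    ``L_s * m_{g,class(s)}`` and variance ``mu + phi_g * mu**2``.  The
    default class sizes mirror a test cohort of 10 ATC, 6 PTC, 6 FTC and
    6 normal-thyroid samples.  Spiked markers emulate de novo expression:
    near-zero mean FPM in every non-ATC class and a ``spike_fold_change``
    induction in ATC, with a low relative standard deviation in ATC.
    Decoys come in two flavours: genes that pass the expression filters
    but have a high RSD in ATC, and genes whose non-ATC expression is too
    high to count as de novo.
    """

    n_genes: int = 2000
    n_samples_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"ATC": 10, "PTC": 6, "FTC": 6, "NT": 6}
    )
    baseline_logmean_mu: float = 6.0
    baseline_logmean_sigma: float = 1.5
    #: (shape, scale) of the Gamma distribution of per-gene dispersions phi
    dispersion_shape_params: tuple[float, float] = (2.0, 0.05)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    n_spiked_markers: int = 20
    spike_fold_change: float = 200.0
    spike_noatc_mean_fpm: float = 0.2
    spike_rsd_target: float = 0.2
    n_decoy_markers: int = 20
    #: expected non-ATC mean FPM of "expressed" decoys (fails the < 1 filter)
    decoy_expressed_fpm: float = 5.0
    #: per-gene dispersion of high-RSD decoys in ATC
    decoy_high_rsd_dispersion: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_genes) != self.n_genes or self.n_genes <= 0:
            raise ValueError("n_genes must be a positive integer")
        for cls, n in self.n_samples_per_class.items():
            if cls not in VALID_CLASSES:
                raise ValueError(f"unknown class label {cls!r}")
            if int(n) != n or n <= 0:
                raise ValueError(f"class {cls!r} requests {n} samples; need a positive integer")
        if not (self.spike_fold_change > 50):
            raise ValueError("spike_fold_change must exceed 50 so spiked genes pass the screen")
        if not (0 < self.spike_noatc_mean_fpm < 1):
            raise ValueError("spike_noatc_mean_fpm must lie in (0, 1)")
        if not (0 < self.spike_rsd_target < 0.5):
            raise ValueError("spike_rsd_target must lie in (0, 0.5)")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValueError("libsize_range must be an increasing pair of positive reals")
        if self.n_spiked_markers < 0 or self.n_decoy_markers < 0:
            raise ValueError("marker counts must be non-negative")
        if self.n_spiked_markers + self.n_decoy_markers > self.n_genes:
            raise ValueError("more spiked+decoy genes than genes in the matrix")
        if any(p <= 0 for p in self.dispersion_shape_params):
            raise ValueError("dispersion_shape_params must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, Var = mu + phi mu^2) sample; phi ~ 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = phi < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix, sample sheet and ground-truth table.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers
    sample_sheet : DataFrame with columns ``sample_id``, ``class``, ``cohort``
    truth : DataFrame with columns ``gene_id``, ``role``,
        ``true_fold_change``, ``true_noatc_mean_fpm``
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = list(config.n_samples_per_class)
    sample_ids: list[str] = []
    sample_class: list[str] = []
    for cls in classes:
        for i in range(int(config.n_samples_per_class[cls])):
            sample_ids.append(f"{cls}_{i + 1:02d}")
            sample_class.append(cls)
    n_samples = len(sample_ids)

    gene_ids = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    base_mean = np.exp(
        rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma, config.n_genes)
    )
    shape, scale = config.dispersion_shape_params
    phi = rng.gamma(shape, scale, config.n_genes)

    # assign roles: spiked first, then decoys split evenly between the two types
    n_special = config.n_spiked_markers + config.n_decoy_markers
    special = rng.choice(config.n_genes, size=n_special, replace=False)
    spiked = special[: config.n_spiked_markers]
    decoys = special[config.n_spiked_markers :]
    n_high_rsd = len(decoys) // 2 + len(decoys) % 2
    decoy_high = decoys[:n_high_rsd]
    decoy_expr = decoys[n_high_rsd:]

    roles = np.full(config.n_genes, ROLE_BACKGROUND, dtype=object)
    roles[spiked] = ROLE_SPIKED
    roles[decoy_high] = ROLE_DECOY_HIGH_RSD
    roles[decoy_expr] = ROLE_DECOY_EXPRESSED

    # per-class expected means; FPM targets are converted to count units via
    # the background library total, so 1 FPM unit ~ base_total / 1e6 counts
    background = roles == ROLE_BACKGROUND
    base_total = base_mean[background].sum()
    unit = base_total / 1e6  # expected counts per FPM unit

    mean_by_class = {cls: base_mean.copy() for cls in classes}
    truth_fc = np.ones(config.n_genes)
    truth_noatc_fpm = np.full(config.n_genes, np.nan)

    def set_profile(idx: np.ndarray, noatc_fpm: float, fold: float) -> None:
        for cls in classes:
            mean_by_class[cls][idx] = noatc_fpm * unit
        if "ATC" in mean_by_class:
            mean_by_class["ATC"][idx] = fold * noatc_fpm * unit
        truth_fc[idx] = fold
        truth_noatc_fpm[idx] = noatc_fpm

    set_profile(spiked, config.spike_noatc_mean_fpm, config.spike_fold_change)
    set_profile(decoy_high, config.spike_noatc_mean_fpm, config.spike_fold_change)
    set_profile(decoy_expr, config.decoy_expressed_fpm, config.spike_fold_change)
    truth_noatc_fpm[background] = base_mean[background] / unit

    # dispersion overrides: spiked markers get a low-variance ATC profile,
    # high-RSD decoys an overdispersed one; CV^2 = 1/mu + phi
    atc_mean_spiked = config.spike_fold_change * config.spike_noatc_mean_fpm * unit
    phi[spiked] = max(config.spike_rsd_target**2 - 1.0 / max(atc_mean_spiked, 1.0), 1e-4)
    phi[decoy_high] = config.decoy_high_rsd_dispersion

    lib_lo, lib_hi = config.libsize_range
    lib_factor = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), n_samples))

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    for j, cls in enumerate(sample_class):
        mu = mean_by_class[cls] * lib_factor[j]
        counts[:, j] = _nb_draw(rng, mu, phi)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "class": sample_class, "cohort": "simulated"}
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "true_fold_change": truth_fc,
            "true_noatc_mean_fpm": truth_noatc_fpm,
        }
    )
    return counts_df, sheet, truth


@dataclass
class IHCCohortConfig:
    """Parameters of a simulated immunohistochemistry cohort.

    ``positivity_rate`` maps (tumor_class, marker) to the probability that
    a sample shows any detectable staining.  Positive samples draw their
    percent-at-intensity vector (intensities 0..3) from a Dirichlet and
    rescale it to sum to 100; negative samples are 100% intensity 0.
    """

    cohort_name: str = "simulated"
    n_per_class: Mapping[str, int] = field(default_factory=lambda: {"ATC": 10, "PTC": 6, "FTC": 6})
    positivity_rate: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: Dirichlet concentration over intensities 0..3 for positive samples
    intensity_alpha: tuple[float, float, float, float] = (0.5, 1.5, 2.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        for (cls, marker), rate in self.positivity_rate.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"positivity_rate[{cls!r}, {marker!r}] = {rate} outside [0, 1]")
        for cls, n in self.n_per_class.items():
            if int(n) != n or n <= 0:
                raise ValueError(f"class {cls!r} requests {n} samples; need a positive integer")
        if any(a <= 0 for a in self.intensity_alpha):
            raise ValueError("intensity_alpha must be positive")


def simulate_ihc_cohort(config: IHCCohortConfig) -> pd.DataFrame:
    """Simulate per-sample IHC records for every (class, marker) pair.

    Returns a DataFrame with columns ``sample_id``, ``cohort``,
    ``tumor_class``, ``marker`` and ``pct_intensity_0`` .. ``pct_intensity_3``
    (each row summing to 100).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = sorted({m for (_, m) in config.positivity_rate})
    rows = []
    for cls, n in config.n_per_class.items():
        for i in range(int(n)):
            sid = f"{config.cohort_name}_{cls}_{i + 1:04d}"
            for marker in markers:
                rate = config.positivity_rate.get((cls, marker), 0.0)
                if rng.random() < rate:
                    pct = rng.dirichlet(config.intensity_alpha) * 100.0
                else:
                    pct = np.array([100.0, 0.0, 0.0, 0.0])
                rows.append(
                    {
                        "sample_id": sid,
                        "cohort": config.cohort_name,
                        "tumor_class": cls,
                        "marker": marker,
                        "pct_intensity_0": pct[0],
                        "pct_intensity_1": pct[1],
                        "pct_intensity_2": pct[2],
                        "pct_intensity_3": pct[3],
                    }
                )
    return pd.DataFrame(rows)


def make_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (15, 100),
    enriched_set_spec: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene-set collection over ``gene_ids``, GMT-serializable.

    ``enriched_set_spec`` optionally adds one named set with exactly the
    given members (e.g. the simulated spiked markers), so that downstream
    enrichment has a known positive.
    """
    gene_ids = list(gene_ids)
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("set_size_range must be an increasing pair of positive integers")
    if hi > len(gene_ids):
        raise ValueError(f"set size {hi} exceeds the {len(gene_ids)}-gene universe")
    rng = np.random.default_rng(seed)
    collection: dict[str, list[str]] = {}
    if enriched_set_spec is not None:
        name, members = enriched_set_spec
        members = list(members)
        if not set(members) <= set(gene_ids):
            raise ValueError("enriched set contains genes outside the universe")
        collection[name] = members
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(gene_ids), size=size, replace=False)
        collection[f"RANDOM_SET_{k + 1:03d}"] = [gene_ids[i] for i in sorted(idx)]
    return collection
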