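"""Seeded generator of abundance matrices with the variance structure the
median polish of ratio assumes.

The observation model is multiplicative (log2-additive)::

    log2 x_ij = latent_ij + beta_i,k(j) + lambda_j + eps_ij   (+ GIS terms)

* ``latent_ij`` — feature base level drawn log-normal over several orders
  of magnitude, plus per-subject biological deviation, plus a group fold
  change on a spiked feature subset;
* ``beta`` — per feature x batch multiplier (the batch effect);
* ``lambda`` — per-sample loading factor;
* ``eps`` — technical noise.

GIS (global internal standard) columns carry the log2 of the *arithmetic
mean* of the case samples' latent abundances (a pooled equal mixture),
optionally distorted by a systematic prep offset shared across batches
(emulating separately digested GIS), a per feature x batch defect, and
sparse gross contamination outliers in individual GIS channels.  Random or
batch-wise missingness is masked last.

Every stochastic component is reconstructible from :class:`GroundTruth`,
enabling parameter-recovery evaluation.  The RNG is NumPy's PCG64 via
``default_rng``; fixed seed gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import qc

__all__ = [
    "SimulationDesign",
    "MultiplatformDesign",
    "GroundTruth",
    "simulate_dataset",
    "make_multiplatform",
    "evaluate_recovery",
    "RecoveryMetrics",
    "STANDARD_BENCHMARK",
    "DEFECT_BENCHMARK",
    "DIFFERENTIAL_BENCHMARK",
    "REPLICATE_BENCHMARK",
    "BENCHMARK_SEEDS",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a simulated multi-batch experiment.

    All effect sizes are SDs in log2 units unless noted.  Defaults are a
    neutral, effect-free design; the named benchmark designs below fix the
    regimes used for evaluation.
    """

    n_features: int = 1000
    n_batches: int = 10
    samples_per_batch: int = 8     # non-GIS (case) channels per batch
    gis_per_batch: int = 2
    #: decades spanned (+-2 SD) by the log-normal feature base abundances
    dynamic_range_orders: float = 4.0
    base_log2_center: float = 20.0
    batch_effect_sd: float = 0.0   # per feature x batch
    loading_sd: float = 0.0        # per sample
    technical_noise_sd: float = 0.0
    subject_sd: float = 0.0        # inter-individual biological deviation
    groups: tuple = ("case", "control")
    spike_fraction: float = 0.0    # fraction of features with a group effect
    spike_log2fc: float = 1.0      # fold change added to the first group
    gis_defect_sd: float = 0.0     # per feature x batch, GIS channels only
    gis_offset_sd: float = 0.0     # per feature, shared by all GIS channels
    gis_outlier_frac: float = 0.0  # per feature x GIS channel contamination rate
    gis_outlier_log2_range: tuple = (6.0, 12.0)
    missing_frac_random: float = 0.0
    missing_batchwise: float = 0.0  # per feature x batch whole-dropout prob
    intensity_dependent_missingness: bool = False
    replicate_pairs: int = 0       # subjects duplicated into a second batch
    seed: int = 0

    def validate(self) -> None:
        for name in ("batch_effect_sd", "loading_sd", "technical_noise_sd",
                     "subject_sd", "gis_defect_sd", "gis_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("spike_fraction", "missing_frac_random", "missing_batchwise",
                     "gis_outlier_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        slots = self.n_batches * self.samples_per_batch
        if 2 * self.replicate_pairs > slots:
            raise ValueError("replicate_pairs exceeds available case slots")
        if self.replicate_pairs and self.n_batches < 2:
            raise ValueError("replicate pairs need >= 2 batches")


@dataclass(frozen=True)
class MultiplatformDesign:
    """Parameters of a multi-platform (transposed-mode) experiment.

    Each platform observes a monotone power-law transform of a shared
    latent proteome: ``log2 y = offset + exponent * log2 x + noise``.  A
    bridging subset of accessions appears on every platform; the data are
    complete (no missingness), matching the regime in which transposed
    harmonization is defined.
    """

    n_samples: int = 35
    platforms: tuple = ("MS", "PEA", "APT")
    features_per_platform: int = 100
    n_shared: int = 20
    exponent_range: tuple = (0.6, 1.4)
    offset_sd: float = 2.0
    platform_noise_sd: float = 0.2
    dynamic_range_orders: float = 4.0
    base_log2_center: float = 20.0
    subject_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.platforms) < 2:
            raise ValueError("need >= 2 platforms")
        if self.n_shared > self.features_per_platform:
            raise ValueError("bridging set larger than the smallest platform panel")


@dataclass
class GroundTruth:
    """Stored stochastic components of a simulated dataset.

    ``observed = latent * batch_multiplier * loading * noise (* gis terms)``
    holds exactly before missingness masking.
    """

    latent: pd.DataFrame            # features x samples, batch-free abundance
    batch_multipliers: pd.DataFrame  # features x batches (linear scale)
    loadings: pd.Series             # per sample (linear scale)
    noise: pd.DataFrame             # features x samples (linear scale)
    gis_multipliers: pd.DataFrame   # features x samples; 1 for non-GIS columns
    spiked_features: list
    true_log2fc: pd.Series  # signed, indexed by spiked feature id
    replicate_map: dict             # sample -> replicate partner sample
    mask: pd.DataFrame              # True where masked to missing
    design: SimulationDesign | None = None
    annotation: pd.DataFrame | None = None

    def reconstruct(self) -> pd.DataFrame:
        """Pre-masking observed abundance from the stored components."""
        obs = (
            self.latent
            * self.batch_multipliers.loc[:, self.annotation["batch"]].to_numpy()
            * self.loadings.to_numpy()[None, :]
            * self.noise
            * self.gis_multipliers
        )
        return obs


def _assign_slots(design: SimulationDesign, rng: np.random.Generator):
    """Distribute subjects over case slots; replicated subjects get two
    slots in different batches."""
    slots = design.n_batches * design.samples_per_batch
    rp = design.replicate_pairs
    n_subjects = slots - rp
    perm = rng.permutation(n_subjects)
    subj_of_slot = np.empty(slots, dtype=int)
    # replicated subjects: first copy in slot p, second in slot p + slots//2
    # (guaranteed different batch since slots//2 >= samples_per_batch when
    # n_batches >= 2)
    rep_subjects = perm[:rp]
    subj_of_slot[:rp] = rep_subjects
    half = slots // 2
    subj_of_slot[half:half + rp] = rep_subjects
    rest = [i for i in range(slots) if not (i < rp or half <= i < half + rp)]
    subj_of_slot[rest] = perm[rp:]
    return subj_of_slot, n_subjects, rep_subjects


def simulate_dataset(design: SimulationDesign):
    """Draw one dataset.

    Returns ``(abundance, annotation, ground_truth)`` where abundance is a
    feature x sample DataFrame (``NaN`` for masked values) and annotation
    carries ``batch``, ``is_gis``, ``group`` and ``subject`` columns.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    nf = design.n_features
    nb = design.n_batches
    spb = design.samples_per_batch
    gpb = design.gis_per_batch
    n_s = nb * (spb + gpb)
    feature_ids = [f"F{i:05d}" for i in range(nf)]
    batch_names = [f"b{k + 1:02d}" for k in range(nb)]

    # --- sample layout ---------------------------------------------------
    batch_of = np.repeat(np.arange(nb), spb + gpb)
    is_gis = np.tile(np.r_[np.zeros(spb, bool), np.ones(gpb, bool)], nb)
    case_cols = np.flatnonzero(~is_gis)
    subj_of_slot, n_subjects, rep_subjects = _assign_slots(design, rng)
    subj_of = np.full(n_s, -1)
    subj_of[case_cols] = subj_of_slot
    # groups are balanced within batch (the regime the polish assumes);
    # replicated subjects keep their group in the second batch
    group_of_subject = np.full(n_subjects, None, dtype=object)
    counts = {b: {g: 0 for g in design.groups} for b in range(nb)}
    for slot, subj in enumerate(subj_of_slot):
        b = slot // spb
        if group_of_subject[subj] is None:
            g = min(design.groups, key=lambda g: (counts[b][g], design.groups.index(g)))
            group_of_subject[subj] = g
        counts[b][group_of_subject[subj]] += 1
    group = np.full(n_s, "GIS", dtype=object)
    group[case_cols] = group_of_subject[subj_of_slot]

    sample_ids = []
    seen = {}
    for j in range(n_s):
        if is_gis[j]:
            sample_ids.append(f"GIS.{batch_names[batch_of[j]]}.{j}")
        else:
            s = subj_of[j]
            seen[s] = seen.get(s, 0) + 1
            sample_ids.append(f"S{s:03d}" + (f".rep{seen[s]}" if seen[s] > 1 else ""))

    # --- latent abundance ------------------------------------------------
    base = rng.normal(design.base_log2_center,
                      design.dynamic_range_orders * np.log2(10.0) / 4.0, nf)
    n_spiked = int(round(design.spike_fraction * nf))
    spiked = np.sort(rng.choice(nf, n_spiked, replace=False))
    fc = np.zeros(nf)
    # spikes alternate up/down so neither group's sample medians shift;
    # one-directional spikes would bleed into the column-centering medians
    fc[spiked] = design.spike_log2fc * np.where(np.arange(n_spiked) % 2 == 0, 1.0, -1.0)
    subj_dev = rng.normal(0.0, design.subject_sd, (nf, n_subjects))
    lat_subject = (
        base[:, None]
        + subj_dev
        + fc[:, None] * (group_of_subject == design.groups[0])[None, :]
    )
    gis_latent = np.log2(np.mean(2.0 ** lat_subject, axis=1))  # pooled mixture
    lat_log2 = np.empty((nf, n_s))
    lat_log2[:, case_cols] = lat_subject[:, subj_of_slot]
    lat_log2[:, is_gis] = gis_latent[:, None]

    # --- technical layers ------------------------------------------------
    beta = rng.normal(0.0, design.batch_effect_sd, (nf, nb))
    lam = rng.normal(0.0, design.loading_sd, n_s)
    eps = rng.normal(0.0, design.technical_noise_sd, (nf, n_s))
    gis_log2 = np.zeros((nf, n_s))
    if design.gis_offset_sd > 0:
        offset = rng.normal(0.0, design.gis_offset_sd, nf)
        gis_log2[:, is_gis] += offset[:, None]
    if design.gis_defect_sd > 0:
        defect = rng.normal(0.0, design.gis_defect_sd, (nf, nb))
        gis_log2[:, is_gis] += defect[:, batch_of[is_gis]]
    if design.gis_outlier_frac > 0:
        gcols = np.flatnonzero(is_gis)
        hit = rng.random((nf, gcols.size)) < design.gis_outlier_frac
        lo, hi = design.gis_outlier_log2_range
        mag = rng.uniform(lo, hi, (nf, gcols.size))
        gis_log2[:, gcols] += hit * mag

    log2x = lat_log2 + beta[:, batch_of] + lam[None, :] + eps + gis_log2
    observed = 2.0 ** log2x

    # --- missingness (masked last) ---------------------------------------
    mask = np.zeros((nf, n_s), bool)
    if design.missing_frac_random > 0:
        if design.intensity_dependent_missingness:
            # left-tail biased: masking probability decays with within-row rank
            ranks = np.argsort(np.argsort(log2x, axis=1), axis=1) / (n_s - 1)
            p = design.missing_frac_random * 2.0 * (1.0 - ranks)
            mask |= rng.random((nf, n_s)) < np.clip(p, 0, 1)
        else:
            mask |= rng.random((nf, n_s)) < design.missing_frac_random
    if design.missing_batchwise > 0:
        drop = rng.random((nf, nb)) < design.missing_batchwise
        mask |= drop[:, batch_of]

    matrix = pd.DataFrame(np.where(mask, np.nan, observed),
                          index=pd.Index(feature_ids, name="feature_id"),
                          columns=sample_ids)
    annotation = pd.DataFrame(
        {
            "batch": np.array(batch_names)[batch_of],
            "is_gis": is_gis,
            "group": group,
            "subject": np.where(subj_of >= 0,
                                np.array([f"S{s:03d}" for s in range(max(n_subjects, 1))]
                                         )[np.maximum(subj_of, 0)], ""),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    replicate_map = {}
    for s in rep_subjects:
        cols = [sample_ids[j] for j in case_cols[subj_of_slot == s]]
        replicate_map[cols[0]] = cols[1]

    truth = GroundTruth(
        latent=pd.DataFrame(2.0 ** lat_log2, index=matrix.index, columns=sample_ids),
        batch_multipliers=pd.DataFrame(2.0 ** beta, index=matrix.index,
                                       columns=batch_names),
        loadings=pd.Series(2.0 ** lam, index=sample_ids, name="loading"),
        noise=pd.DataFrame(2.0 ** eps, index=matrix.index, columns=sample_ids),
        gis_multipliers=pd.DataFrame(2.0 ** gis_log2, index=matrix.index,
                                     columns=sample_ids),
        spiked_features=[feature_ids[i] for i in spiked],
        true_log2fc=pd.Series(fc[spiked], index=[feature_ids[i] for i in spiked],
                              name="true_log2fc"),
        replicate_map=replicate_map,
        mask=pd.DataFrame(mask, index=matrix.index, columns=sample_ids),
        design=design,
        annotation=annotation,
    )
    return matrix, annotation, truth


def make_multiplatform(design: MultiplatformDesign):
    """Simulate a combined multi-platform matrix for transposed-mode
    harmonization.

    Returns ``(matrix, platform_of_feature, common_feature_ids)``; rows are
    ``accession@platform`` assays, columns are samples, data are complete.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_total_acc = design.n_shared + len(design.platforms) * (
        design.features_per_platform - design.n_shared
    )
    accessions = [f"P{i:05d}" for i in range(n_total_acc)]
    shared = accessions[: design.n_shared]
    base = rng.normal(design.base_log2_center,
                      design.dynamic_range_orders * np.log2(10.0) / 4.0, n_total_acc)
    latent = base[:, None] + rng.normal(0.0, design.subject_sd,
                                        (n_total_acc, design.n_samples))
    sample_ids = [f"S{j:03d}" for j in range(design.n_samples)]

    rows, row_ids, plat_of = [], [], {}
    cursor = design.n_shared
    for p in design.platforms:
        exclusive = accessions[cursor: cursor + design.features_per_platform - design.n_shared]
        cursor += design.features_per_platform - design.n_shared
        panel = shared + exclusive
        idx = [accessions.index(a) for a in panel]
        expo = rng.uniform(*design.exponent_range)
        offset = rng.normal(0.0, design.offset_sd)
        noise = rng.normal(0.0, design.platform_noise_sd,
                           (len(panel), design.n_samples))
        obs = offset + expo * latent[idx] + noise
        rows.append(2.0 ** obs)
        row_ids.extend(f"{a}@{p}" for a in panel)
        plat_of.update({f"{a}@{p}": p for a in panel})
    matrix = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(row_ids, name="feature_id"),
                          columns=sample_ids)
    return matrix, pd.Series(plat_of, name="platform"), list(shared)


@dataclass
class RecoveryMetrics:
    """How well a correction recovered the simulated ground truth."""

    median_batch_variance_fraction: float
    spike_log2fc_rmse: float
    median_batch_dispersion_log2: float
    n_features: int
    n_spiked: int


def evaluate_recovery(corrected: pd.DataFrame, ground_truth: GroundTruth,
                      annotation: pd.DataFrame | None = None) -> RecoveryMetrics:
    """Score a corrected matrix against the generator's ground truth.

    * median per-feature variance fraction explained by batch (non-GIS
      samples, log2 scale);
    * RMSE between estimated (group-mean difference) and true spiked
      log2 fold changes;
    * median across features of the SD over batches of the within-batch
      mean log2(corrected / latent) — the residual batch dispersion, 0 for
      a perfect correction.
    """
    ann = ground_truth.annotation if annotation is None else annotation
    if not corrected.index.equals(ground_truth.latent.index):
        raise ValueError("feature ids of corrected matrix do not match ground truth")
    ann = ann.loc[list(corrected.columns)]
    case = ~ann["is_gis"].to_numpy(bool)
    log2c = np.log2(corrected)
    vf = qc.variance_explained(log2c.loc[:, case], ann.loc[case], ["batch"])
    median_bf = float(vf["batch"].median())

    groups = ground_truth.design.groups if ground_truth.design else ("case", "control")
    ga = (ann["group"] == groups[0]).to_numpy() & case
    gb = (ann["group"] == groups[1]).to_numpy() & case
    sp = ground_truth.spiked_features
    if sp and ga.any() and gb.any():
        est = (log2c.loc[sp, ga].mean(axis=1) - log2c.loc[sp, gb].mean(axis=1))
        truth = ground_truth.true_log2fc.loc[sp]
        rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    else:
        rmse = float("nan")

    ratio = np.log2(corrected.loc[:, case].to_numpy(float)
                    / ground_truth.latent.loc[:, corrected.columns[case]].to_numpy(float))
    batches = ann.loc[case, "batch"].to_numpy()
    per_batch = np.stack(
        [np.nanmean(ratio[:, batches == b], axis=1) for b in pd.unique(batches)], axis=1
    )
    disp = np.nanstd(per_batch, axis=1, ddof=1)
    return RecoveryMetrics(
        median_batch_variance_fraction=median_bf,
        spike_log2fc_rmse=rmse,
        median_batch_dispersion_log2=float(np.nanmedian(disp)),
        n_features=corrected.shape[0],
        n_spiked=len(sp),
    )


#: The repo-fixed evaluation designs. ``STANDARD_BENCHMARK`` is the core
#: regime: 1,000 features, 10 batches of 8 cases + 2 GIS (100 samples),
#: batch effects of 1.0 log2 SD, 0.5 loading SD, 0.3 technical noise,
#: modest inter-individual biology and 10% spiked features at 1 log2 FC.
STANDARD_BENCHMARK = SimulationDesign(
    n_features=1000, n_batches=10, samples_per_batch=8, gis_per_batch=2,
    batch_effect_sd=1.0, loading_sd=0.5, technical_noise_sd=0.3,
    subject_sd=0.15, spike_fraction=0.1, spike_log2fc=1.0, seed=20230412,
)

#: Standard benchmark with a defective GIS (separately processed pools),
#: the regime where naive GIS ratio fails but GIS+non-GIS tuning succeeds.
DEFECT_BENCHMARK = replace(STANDARD_BENCHMARK, gis_defect_sd=0.5)

#: Half-size twin for differential-abundance recovery: 5 batches -> 40
#: cases = 20 per group; within-group SD equals the technical noise.
DIFFERENTIAL_BENCHMARK = replace(STANDARD_BENCHMARK, n_batches=5, subject_sd=0.0)

#: Technical-replicate benchmark (correlation boosting): 30 subjects each
#: measured in two of 12 batches, 3 GIS per batch with a systematic prep
#: offset and sparse gross contamination of individual GIS channels.
REPLICATE_BENCHMARK = SimulationDesign(
    n_features=400, n_batches=12, samples_per_batch=5, gis_per_batch=3,
    batch_effect_sd=0.6, loading_sd=0.3, technical_noise_sd=0.3,
    subject_sd=0.3, spike_fraction=0.0, gis_offset_sd=0.2,
    gis_outlier_frac=0.02, gis_outlier_log2_range=(6.0, 12.0),
    replicate_pairs=30, seed=20230412,
)

#: Seeds for replicated benchmark claims.
BENCHMARK_SEEDS = tuple(20230412 + i for i in range(5))
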