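"""Synthetic cohort, TMT abundance, and SRM data generators with known ground truth.

The generators emulate the statistical structure of a two-diagnosis
(control / Alzheimer's disease), two-race (Caucasian / African American)
CSF cohort profiled by 16-plex isobaric labelling: four clinical groups
with realistic trait distributions, planted co-expression modules whose
latent summary profiles carry diagnosis/race/interaction effects,
per-batch technical shifts anchored by a pooled internal-standard channel
in every batch, block-wise missingness, and targeted-peptide (SRM)
area-ratio tables with pooled quality-control replicates.  Every stage of
the downstream pipeline can therefore be tested against planted truth
without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidSpecError
from .matrix import AbundanceMatrix

__all__ = [
    "CohortSpec",
    "ModulePlantSpec",
    "BatchDesign",
    "GroundTruth",
    "generate_cohort",
    "allocate_batches",
    "generate_tmt",
    "plant_outliers",
    "generate_srm",
    "SRMDataset",
    "affine_matched_groups",
]

GROUPS = (("CT", "Cau"), ("CT", "AA"), ("AD", "Cau"), ("AD", "AA"))

#: TMTpro channel labels: 13 sample channels, the internal-standard channel
#: (126) and the two biomarker pool channels (133C negative, 134N positive).
SAMPLE_CHANNELS = (
    "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N",
)
GIS_CHANNEL = "126"
POOL_NEG_CHANNEL = "133C"
POOL_POS_CHANNEL = "134N"

ABETA_SATURATION = 1700.0  # pg/mL assay ceiling; values at/above are censored


def _default_group_map(values):
    return {g: v for g, v in zip(GROUPS, values)}


@dataclass
class CohortSpec:
    """Per-group cohort parameters.

    Defaults give a realistic four-group cohort: group sizes 53/52/47/51
    (CT-Cau, CT-AA, AD-Cau, AD-AA) with per-group mean +/- SD for age,
    MoCA, and the fluid biomarkers (pg/mL).
    """

    group_sizes: dict = field(default_factory=lambda: _default_group_map((53, 52, 47, 51)))
    age_mean_sd: dict = field(default_factory=lambda: _default_group_map(
        ((65.0, 8.0), (64.0, 8.0), (68.0, 9.0), (68.0, 9.0))))
    sex_fraction_female: dict = field(default_factory=lambda: _default_group_map(
        (33 / 53, 33 / 52, 29 / 47, 32 / 51)))
    trait_means_sds: dict = field(default_factory=lambda: {
        "moca": _default_group_map(((26.0, 2.0), (25.0, 3.0), (16.0, 6.0), (14.0, 6.0))),
        "abeta42": _default_group_map(
            ((1195.2, 262.0), (1021.4, 301.1), (558.2, 169.9), (483.4, 151.8))),
        "ttau": _default_group_map(
            ((186.2, 61.6), (158.5, 56.5), (423.7, 189.2), (301.5, 134.8))),
        "ptau181": _default_group_map(
            ((16.6, 5.6), (14.1, 4.9), (43.3, 20.8), (30.1, 14.1))),
    })
    # APOE e4 carriage is assigned by diagnosis only (carrier distribution
    # did not differ by race); comorbidity rates shared across groups.
    apoe4_fraction: dict = field(default_factory=lambda: _default_group_map(
        (0.25, 0.25, 0.55, 0.55)))
    comorbidity_fractions: dict = field(default_factory=lambda: {
        "hypertension": 0.45, "diabetes": 0.15,
        "dyslipidemia": 0.35, "cerebrovascular": 0.10,
    })
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise InvalidSpecError(f"group size for {g} must be positive, got {n}")
        for g, (_, sd) in self.age_mean_sd.items():
            if sd < 0:
                raise InvalidSpecError(f"negative age SD for {g}")
        for trait, per_group in self.trait_means_sds.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise InvalidSpecError(f"negative SD for {trait} in {g}")
        for name, fracs in (("sex", self.sex_fraction_female),
                            ("apoe4", self.apoe4_fraction)):
            for g, f in fracs.items():
                if not 0.0 <= f <= 1.0:
                    raise InvalidSpecError(f"{name} fraction for {g} outside [0,1]")
        for name, f in self.comorbidity_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError(f"comorbidity fraction {name} outside [0,1]")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Gaussian draws truncated to [lo, hi]; degenerate when sd == 0."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a = (lo - mean) / sd if np.isfinite(lo) else -np.inf
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one trait record per sample.

    Returns a DataFrame indexed by sample id with diagnosis, race, sex,
    age, MoCA (integer score), fluid biomarkers (Abeta42 censored at the
    assay saturation ceiling with an ``abeta42_saturated`` flag), APOE e4
    carrier flag and comorbidity flags.  Identical seeds give identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    i = 0
    for (dx, race) in GROUPS:
        n = spec.group_sizes[(dx, race)]
        am, asd = spec.age_mean_sd[(dx, race)]
        age = _truncated_normal(rng, am, asd, 40.0, np.inf, n)
        moca = np.round(_truncated_normal(
            rng, *spec.trait_means_sds["moca"][(dx, race)], 0.0, 30.0, n))
        abeta = _truncated_normal(
            rng, *spec.trait_means_sds["abeta42"][(dx, race)], 1e-6, np.inf, n)
        ttau = _truncated_normal(
            rng, *spec.trait_means_sds["ttau"][(dx, race)], 1e-6, np.inf, n)
        ptau = _truncated_normal(
            rng, *spec.trait_means_sds["ptau181"][(dx, race)], 1e-6, np.inf, n)
        female = rng.random(n) < spec.sex_fraction_female[(dx, race)]
        apoe4 = rng.random(n) < spec.apoe4_fraction[(dx, race)]
        comorb = {c: rng.random(n) < f
                  for c, f in spec.comorbidity_fractions.items()}
        saturated = abeta >= ABETA_SATURATION
        abeta = np.minimum(abeta, ABETA_SATURATION)
        for j in range(n):
            rec = {
                "sample_id": f"S{i + j + 1:03d}",
                "diagnosis": dx, "race": race,
                "sex": "F" if female[j] else "M",
                "age": float(age[j]), "moca": float(moca[j]),
                "abeta42": float(abeta[j]),
                "abeta42_saturated": bool(saturated[j]),
                "ttau": float(ttau[j]), "ptau181": float(ptau[j]),
                "apoe4": bool(apoe4[j]),
            }
            rec.update({c: bool(v[j]) for c, v in comorb.items()})
            records.append(rec)
        i += n
    return pd.DataFrame(records).set_index("sample_id")


@dataclass
class ModulePlantSpec:
    """Planted co-expression structure for the abundance generator.

    Each module has a latent per-sample summary profile built from group
    effects plus unit-variance noise; member proteins load on it with a
    loading drawn from ``loading_range``.  ``effect_map`` entries are
    per-module coefficients (log2 units) for diagnosis (AD=1), race (AA=1),
    their interaction, age (per year, centred) and sex (female=1).  The
    default eight modules emulate the observed module-trait structure:
    a large synaptic-like module lower in AD and lower still in African
    Americans with AD, metabolic modules raised in AD with a larger rise
    in Caucasians, vascular modules raised in African Americans at
    baseline, and disease modules shared across race.
    """

    module_sizes: tuple = (370, 250, 180, 120, 80, 60, 40, 30)
    loading_range: tuple = (0.6, 0.95)
    effect_map: tuple = (
        {"diagnosis": -0.8, "race": -0.4, "interaction": -0.5, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.0, "race": 0.6, "interaction": 0.0, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.9, "race": 0.0, "interaction": 0.0, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.7, "race": 0.0, "interaction": -0.5, "age": 0.0, "sex": 0.0},
        {"diagnosis": -0.6, "race": -0.3, "interaction": 0.0, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.0, "race": 0.4, "interaction": 0.0, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.9, "race": 0.0, "interaction": 0.0, "age": 0.0, "sex": 0.0},
        {"diagnosis": 0.3, "race": 0.0, "interaction": 0.0, "age": 0.0, "sex": 0.0},
    )
    noise_sd: float = 0.5
    n_background_proteins: int = 670

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidSpecError("loadings must lie in (0, 1]")
        if len(self.effect_map) != self.n_modules:
            raise InvalidSpecError("effect_map must have one entry per module")
        for eff in self.effect_map:
            if not all(np.isfinite(list(eff.values()))):
                raise InvalidSpecError("effect coefficients must be finite")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.n_background_proteins < 0:
            raise InvalidSpecError("n_background_proteins must be >= 0")


@dataclass
class BatchDesign:
    """Multiplexing layout: batches, channels, and technical-effect levels."""

    n_batches: int = 16
    sample_channels: tuple = SAMPLE_CHANNELS
    gis_channel: str = GIS_CHANNEL
    pool_neg_channel: str = POOL_NEG_CHANNEL
    pool_pos_channel: str = POOL_POS_CHANNEL
    batch_shift_sd: float = 0.4
    batchwise_missing_prob: float = 0.05

    def validate(self) -> None:
        if self.n_batches < 1:
            raise InvalidSpecError("need at least one batch")
        if not 0.0 <= self.batchwise_missing_prob <= 1.0:
            raise InvalidSpecError("missing probability outside [0,1]")
        if self.batch_shift_sd < 0:
            raise InvalidSpecError("batch_shift_sd must be >= 0")

    def capacity(self) -> int:
        return self.n_batches * len(self.sample_channels)


def allocate_batches(traits: pd.DataFrame, design: BatchDesign) -> pd.DataFrame:
    """Deterministic stratified allocation of samples to batch/channel slots.

    Samples are ordered by diagnosis, race, sex, then age and dealt in a
    snake pattern across batches so each batch is balanced for the four
    traits (a simple stand-in for automated multi-trait randomization).
    Returns a DataFrame indexed by sample id with ``batch`` and ``channel``.
    """
    design.validate()
    if len(traits) > design.capacity():
        raise InvalidSpecError(
            f"{len(traits)} samples exceed design capacity {design.capacity()}")
    order = traits.sort_values(["diagnosis", "race", "sex", "age"]).index
    batches = np.empty(len(order), dtype=int)
    nb = design.n_batches
    for pos, _ in enumerate(order):
        cycle, slot = divmod(pos, nb)
        batches[pos] = slot if cycle % 2 == 0 else nb - 1 - slot
    rows = []
    counters = {b: 0 for b in range(1, nb + 1)}
    for sid, b0 in zip(order, batches):
        b = b0 + 1
        rows.append({"sample_id": sid, "batch": f"b{b}",
                     "channel": design.sample_channels[counters[b]]})
        counters[b] += 1
    return pd.DataFrame(rows).set_index("sample_id").loc[traits.index]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic abundance matrix."""

    module_membership: pd.Series            # protein -> "M1".."Mk" or "M0"
    eigenprotein_latents: pd.DataFrame      # module x sample latent scores
    loadings: pd.Series                     # protein -> loading (0 for background)
    true_signal: pd.DataFrame               # protein x sample log2 signal, no batch/noise
    pool_levels: pd.DataFrame               # protein x {neg, pos} true log2 level
    planted_outlier_samples: list = field(default_factory=list)
    planted_dep_proteins: dict = field(default_factory=dict)  # contrast -> set

    def validate(self) -> None:
        if not self.module_membership.index.equals(self.true_signal.index):
            raise InvalidSpecError("membership/matrix protein index mismatch")
        if set(self.eigenprotein_latents.columns) != set(self.true_signal.columns):
            raise InvalidSpecError("latent/matrix sample mismatch")


def _module_latents(traits: pd.DataFrame, plant: ModulePlantSpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    dx = (traits["diagnosis"] == "AD").to_numpy(float)
    race = (traits["race"] == "AA").to_numpy(float)
    sex = (traits["sex"] == "F").to_numpy(float)
    age_c = traits["age"].to_numpy(float) - traits["age"].mean()
    lat = np.empty((plant.n_modules, len(traits)))
    for m, eff in enumerate(plant.effect_map):
        mean = (eff["diagnosis"] * dx + eff["race"] * race
                + eff["interaction"] * dx * race
                + eff["age"] * age_c + eff["sex"] * sex)
        lat[m] = mean + rng.standard_normal(len(traits))
    names = [f"M{m + 1}" for m in range(plant.n_modules)]
    return pd.DataFrame(lat, index=names, columns=traits.index)


def generate_tmt(traits: pd.DataFrame, plant: ModulePlantSpec,
                 design: BatchDesign, seed: int = 0,
                 assignment: pd.DataFrame | None = None
                 ) -> tuple[AbundanceMatrix, GroundTruth]:
    """Simulate a log2 protein x channel abundance matrix with planted truth.

    Column ids are ``b<batch>.<channel>`` covering the cohort samples plus,
    per batch, one internal-standard (GIS) channel and two biomarker pool
    channels.  Per protein: value = baseline + loading * module latent +
    per-batch shift + channel noise.  The GIS channel carries the cohort
    average of the protein plus the same batch shift, anchoring batch
    correction; the pool channels carry the average control-like and
    AD-like profiles.  Missingness removes whole protein x batch blocks.
    """
    plant.validate()
    design.validate()
    rng = np.random.default_rng(seed)
    if assignment is None:
        assignment = allocate_batches(traits, design)
    if not set(assignment.index) >= set(traits.index):
        raise InvalidSpecError("assignment does not cover all samples")

    n_mod_prot = int(np.sum(plant.module_sizes))
    n_prot = n_mod_prot + plant.n_background_proteins
    protein_ids = [f"P{i + 1:04d}|Q{i + 1:05d}" for i in range(n_prot)]

    membership = np.array(["M0"] * n_prot, dtype=object)
    start = 0
    for m, size in enumerate(plant.module_sizes):
        membership[start:start + size] = f"M{m + 1}"
        start += size
    membership = pd.Series(membership, index=protein_ids, name="module")

    latents = _module_latents(traits, plant, rng)
    lo, hi = plant.loading_range
    loadings = np.zeros(n_prot)
    loadings[:n_mod_prot] = rng.uniform(lo, hi, n_mod_prot)
    loadings = pd.Series(loadings, index=protein_ids, name="loading")
    baseline = rng.normal(14.0, 2.0, n_prot)

    # protein x sample true (technical-noise-free) signal
    L = np.zeros((n_prot, len(traits)))
    start = 0
    for m in range(plant.n_modules):
        size = plant.module_sizes[m]
        L[start:start + size] = (loadings.to_numpy()[start:start + size, None]
                                 * latents.iloc[m].to_numpy()[None, :])
        start += size
    signal = baseline[:, None] + L
    true_signal = pd.DataFrame(signal, index=protein_ids, columns=traits.index)

    dx = traits["diagnosis"].to_numpy()
    pool_neg = signal[:, dx == "CT"].mean(axis=1)
    pool_pos = signal[:, dx == "AD"].mean(axis=1)
    gis_level = signal.mean(axis=1)
    pool_levels = pd.DataFrame({"neg": pool_neg, "pos": pool_pos}, index=protein_ids)

    batches = [f"b{b + 1}" for b in range(design.n_batches)]
    shifts = rng.normal(0.0, design.batch_shift_sd, (n_prot, design.n_batches))

    columns, roles, col_batch = [], {}, {}
    col_values = {}
    for bi, b in enumerate(batches):
        in_b = assignment.index[assignment["batch"] == b]
        gcol = f"{b}.{design.gis_channel}"
        columns.append(gcol)
        roles[gcol] = "gis"
        col_batch[gcol] = b
        col_values[gcol] = (gis_level + shifts[:, bi]
                            + rng.normal(0.0, plant.noise_sd, n_prot))
        for sid in in_b:
            ch = assignment.loc[sid, "channel"]
            col = f"{b}.{ch}"
            columns.append(col)
            roles[col] = "sample"
            col_batch[col] = b
            si = traits.index.get_loc(sid)
            col_values[col] = (signal[:, si] + shifts[:, bi]
                               + rng.normal(0.0, plant.noise_sd, n_prot))
        for label, level in ((design.pool_neg_channel, pool_neg),
                             (design.pool_pos_channel, pool_pos)):
            col = f"{b}.{label}"
            columns.append(col)
            roles[col] = "pool"
            col_batch[col] = b
            col_values[col] = (level + shifts[:, bi]
                               + rng.normal(0.0, plant.noise_sd, n_prot))

    data = pd.DataFrame(col_values, index=protein_ids)[columns]

    if design.batchwise_missing_prob > 0:
        miss = rng.random((n_prot, design.n_batches)) < design.batchwise_missing_prob
        for bi, b in enumerate(batches):
            cols = [c for c in columns if col_batch[c] == b]
            data.loc[miss[:, bi], cols] = np.nan

    # rename matrix columns sample-wise to sample ids? keep channel ids; the
    # design table maps sample ids to channel columns.
    sample_col_of = {f"{assignment.loc[sid, 'batch']}.{assignment.loc[sid, 'channel']}": sid
                     for sid in assignment.index if sid in traits.index}
    matrix = AbundanceMatrix(
        data=data,
        roles=pd.Series(roles),
        batches=pd.Series(col_batch),
        sample_of_column=pd.Series(sample_col_of),
    )

    dep = {}
    eff = plant.effect_map
    names = [f"M{m + 1}" for m in range(plant.n_modules)]
    cau = {names[m] for m in range(plant.n_modules) if eff[m]["diagnosis"] != 0}
    aa = {names[m] for m in range(plant.n_modules)
          if eff[m]["diagnosis"] + eff[m]["interaction"] != 0}
    dep["AD_vs_CT_Cau"] = set(membership.index[membership.isin(cau)])
    dep["AD_vs_CT_AA"] = set(membership.index[membership.isin(aa)])

    truth = GroundTruth(
        module_membership=membership,
        eigenprotein_latents=latents,
        loadings=loadings,
        true_signal=true_signal,
        pool_levels=pool_levels,
        planted_dep_proteins=dep,
    )
    truth.validate()
    return matrix, truth


def plant_outliers(matrix: AbundanceMatrix, sample_ids, shift_mads: float = 8.0,
                   seed: int = 0) -> AbundanceMatrix:
    """Shift whole samples by ``shift_mads`` x per-protein MAD (global offset).

    Returns a new matrix; used to create known aberrant samples for testing
    outlier detection.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    sample_cols = out.sample_columns
    vals = out.data[sample_cols].to_numpy()
    med = np.nanmedian(vals, axis=1)
    madv = np.nanmedian(np.abs(vals - med[:, None]), axis=1)
    for sid in sample_ids:
        col = out.column_of_sample(sid)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[col] = out.data[col] + sign * shift_mads * madv
    return out


@dataclass
class SRMDataset:
    """Targeted-peptide area-ratio data with pooled QC replicates.

    ``ratios`` are light/heavy total-area ratios (>= 0, complete: a value is
    always assigned for every peptide in every sample).  ``qc_ratios`` holds
    the replicate injections of the AD-biomarker-positive and -negative
    pools; ``qc_pool_of`` labels each replicate column.
    """

    ratios: pd.DataFrame               # peptide x sample
    protein_of: pd.Series              # peptide -> protein id
    qc_ratios: pd.DataFrame            # peptide x qc replicate
    qc_pool_of: pd.Series              # qc column -> "pos"/"neg"
    cv_targets: pd.Series | None = None  # peptide -> generating CV (truth)

    def validate(self) -> None:
        if (self.ratios.to_numpy() < 0).any():
            raise InvalidSpecError("SRM ratios must be non-negative")
        if self.ratios.isna().to_numpy().any():
            raise InvalidSpecError("SRM ratios must be complete")
        if not self.protein_of.index.equals(self.ratios.index):
            raise InvalidSpecError("peptide/protein map mismatch")

    def subset(self, peptides) -> "SRMDataset":
        peptides = list(peptides)
        return SRMDataset(
            ratios=self.ratios.loc[peptides],
            protein_of=self.protein_of.loc[peptides],
            qc_ratios=self.qc_ratios.loc[peptides],
            qc_pool_of=self.qc_pool_of,
            cv_targets=None if self.cv_targets is None else self.cv_targets.loc[peptides],
        )


def generate_srm(truth: GroundTruth, target_proteins=None,
                 peptides_per_protein: tuple = (1, 3),
                 qc_cv_targets=(0.05, 0.30), n_qc_replicates: int = 29,
                 zero_prob: float = 0.005, seed: int = 0) -> SRMDataset:
    """Simulate peptide light/heavy area ratios for targeted proteins.

    Each peptide measures its protein's true log2 level through a fixed
    ionisation/digestion efficiency and multiplicative lognormal noise whose
    sigma is calibrated so the pooled-QC coefficient of variation matches
    the peptide's target CV (sigma = sqrt(ln(1 + CV^2))).  Occasional true
    zeros emulate signal below the detection limit.  Both QC pools are
    replicated ``n_qc_replicates`` times.
    """
    if n_qc_replicates < 2:
        raise InvalidSpecError("need >= 2 QC replicates for a CV")
    rng = np.random.default_rng(seed)
    if target_proteins is None:
        member = truth.module_membership[truth.module_membership != "M0"]
        step = max(1, len(member) // 40)
        target_proteins = list(member.index[::step][:40])
    missing = [p for p in target_proteins if p not in truth.true_signal.index]
    if missing:
        raise InvalidSpecError(f"target proteins absent from truth: {missing[:3]}")

    lo, hi = peptides_per_protein
    if isinstance(qc_cv_targets, (tuple, list)) and len(qc_cv_targets) == 2 \
            and not isinstance(qc_cv_targets, pd.Series):
        cv_lo, cv_hi = qc_cv_targets
        draw_cv = lambda: float(rng.uniform(cv_lo, cv_hi))  # noqa: E731
    else:
        seq = list(qc_cv_targets)
        it = iter(seq * 10_000)
        draw_cv = lambda: float(next(it))  # noqa: E731

    samples = truth.true_signal.columns
    pep_rows, qc_rows, pep_ids, prot_map, cvs = [], [], [], [], []
    for prot in target_proteins:
        npep = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        level = 2.0 ** truth.true_signal.loc[prot].to_numpy()
        level_neg = 2.0 ** truth.pool_levels.loc[prot, "neg"]
        level_pos = 2.0 ** truth.pool_levels.loc[prot, "pos"]
        for j in range(npep):
            pid = f"{prot.split('|')[0]}_pep{j + 1}"
            cv = draw_cv()
            sigma = np.sqrt(np.log1p(cv * cv))
            eff = rng.lognormal(mean=-3.0, sigma=0.5)  # heavy-standard ratio scale
            noise = rng.lognormal(0.0, sigma, len(samples)) if sigma > 0 else 1.0
            vals = level * eff * noise
            zeros = rng.random(len(samples)) < zero_prob
            vals = np.where(zeros, 0.0, vals)
            qn = (rng.lognormal(0.0, sigma, n_qc_replicates) if sigma > 0
                  else np.ones(n_qc_replicates))
            qp = (rng.lognormal(0.0, sigma, n_qc_replicates) if sigma > 0
                  else np.ones(n_qc_replicates))
            qc = np.concatenate([level_neg * eff * qn, level_pos * eff * qp])
            pep_rows.append(vals)
            qc_rows.append(qc)
            pep_ids.append(pid)
            prot_map.append(prot)
            cvs.append(cv)

    qc_cols = ([f"QCneg_{r + 1}" for r in range(n_qc_replicates)]
               + [f"QCpos_{r + 1}" for r in range(n_qc_replicates)])
    ds = SRMDataset(
        ratios=pd.DataFrame(pep_rows, index=pep_ids, columns=samples),
        protein_of=pd.Series(prot_map, index=pep_ids, name="protein"),
        qc_ratios=pd.DataFrame(qc_rows, index=pep_ids, columns=qc_cols),
        qc_pool_of=pd.Series(["neg"] * n_qc_replicates + ["pos"] * n_qc_replicates,
                             index=qc_cols),
        cv_targets=pd.Series(cvs, index=pep_ids, name="cv_target"),
    )
    ds.validate()
    return ds


def affine_matched_groups(means, sds, ns, seed: int = 0, ddof: int = 1):
    """Construct groups whose sample mean and SD exactly equal the targets.

    Draws a Gaussian shape vector per group, standardises it (mean 0,
    SD 1 with the requested ``ddof``), then applies the affine map.  Used
    to rebuild datasets from published summary statistics.
    """
    rng = np.random.default_rng(seed)
    groups = []
    for m, s, n in zip(means, sds, ns):
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=ddof)
        groups.append(m + s * x)
    return groups
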