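"""Synthetic probe-level microarray experiments and RT-qPCR plates.

Emulates a single-color miRNA microarray study of bone-marrow MSC lines
expanded through culture passages: several donors, each hybridized in
triplicate at each passage, 4-8 probe replicates per sequence on every array,
and a set of negative-control probes whose distribution defines the detection
background.  The generative model is additive on the log2 scale,

    log2 signal = baseline(seq) + donor effect(donor, seq)
                  + passage effect(seq, passage) + array offset(array)
                  + sequence-by-array noise + probe-replicate noise,

and raw intensities are emitted as ``2 ** log2`` so that taking log2 of the
raw signal recovers the additive model exactly.  Ground-truth effect sets are
returned alongside the data for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "QpcrSimConfig",
    "GroundTruth",
    "QpcrGroundTruth",
    "simulate_experiment",
    "simulate_qpcr",
    "study_config",
    "study_qpcr_config",
]

#: magnitudes of the passage effects used by :func:`study_config`, as signed
#: fold changes late-vs-early (log2 shifts are derived from these); the P5
#: column is None where the effect only appears at the final passage.
STUDY_P7_FOLDS = [-1.05, -1.39, 1.32, -1.15, 1.26, -1.19, 1.45, 1.49,
                  1.32, -1.22, -1.13, -1.42]
STUDY_P5_FOLDS = [-1.05, -1.33, 1.39, -1.19, 1.24, -1.21, 1.28, 1.38,
                  None, None, None, None]

REFERENCE_TARGETS = ("SNORD61", "SNORD68", "SNORD72", "SNORD95", "SNORD96A")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _signed_fold_to_log2(fold: float) -> float:
    return np.log2(fold) if fold >= 0 else -np.log2(-fold)


@dataclass
class SimulationConfig:
    """Design and noise parameters for one synthetic microarray experiment.

    Defaults reproduce the study conditions: 8 donors at passages P3/P5/P7 in
    triplicate (two donors dropping out early, for 21 donor/passage groups),
    2686 probe sequences for 939 miRNAs with 4-8 on-array probe replicates,
    and 434 negative-control probes per array.
    """

    n_donors: int = 8
    passages: tuple[str, ...] = ("P3", "P5", "P7")
    n_tech_reps: int = 3
    n_sequences: int = 2686
    n_mirnas: int = 939
    probe_reps_range: tuple[int, int] = (4, 8)
    n_negative_controls: int = 434
    #: log2 baseline range for sequences expressed above background
    baseline_log2_range: tuple[float, float] = (5.6, 9.8)
    #: log2 baseline range for sequences at or below background
    background_log2_range: tuple[float, float] = (3.8, 5.1)
    #: fraction of sequences drawn from the expressed component
    expressed_fraction: float = 0.10
    #: scale of the exponential upper tail of expressed baselines; when set,
    #: expressed baselines are background_top + Exp(scale) (clipped at 10),
    #: giving the continuous right-skewed intensity density real arrays show;
    #: ``None`` draws them uniformly from baseline_log2_range instead
    baseline_tail_scale: float | None = 0.9
    #: fraction of sequences expressed in some donors but not all: moderate
    #: baselines with strongly amplified donor effects (donor heterogeneity)
    variable_fraction: float = 0.0
    variable_log2_range: tuple[float, float] = (5.2, 8.0)
    variable_donor_multiplier: float = 3.0
    sigma_probe: float = 0.05
    sigma_array: float = 0.15
    sigma_donor: float = 0.20
    #: per sequence-by-array technical noise; the non-offset part of
    #: between-chip variability (array offsets cancel under quantile
    #: normalization, this term does not)
    sigma_seq_array: float = 0.02
    #: technical variability grows with expression magnitude on real arrays;
    #: sigma_probe and sigma_seq_array are multiplied by
    #: 1 + slope * max(0, baseline - 6.0) per sequence
    sigma_vs_intensity_slope: float = 0.8
    #: optional donor-by-passage interaction: a slice of expressed sequences
    #: whose passage trajectories are donor-specific (large but inconsistent
    #: changes — what the biological-variability filter exists to remove);
    #: off by default so ground-truth recovery invariants stay exact
    interaction_fraction: float = 0.0
    sigma_interaction: float = 0.3
    #: sequence id -> {passage label -> log2 shift}; the ground-truth effects
    passage_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (long_seq, short_seq, log2 offset long-over-short); pairs map to one miRNA
    duplicate_pairs: list[tuple[str, str, float]] | None = None
    n_duplicate_pairs: int = 41
    duplicate_log2_offset: float = 0.74
    n_rrna_trna: int = 11
    negctl_mean: float = 5.29
    negctl_sd: float = 0.11
    #: donor id -> last passage label reached (later arrays are omitted)
    dropout_donors: dict[str, str] = field(default_factory=dict)
    #: array id -> log2 elevation of its negative-control background
    outlier_arrays: dict[str, float] = field(default_factory=dict)
    #: cancer cohort samples hybridized alongside (compared against MSC P3)
    cancer_samples: tuple[str, ...] = ()
    cancer_reps: int = 2
    #: sequence id -> log2 shift in the cancer cohort relative to MSC baseline
    cancer_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def sequence_ids(self) -> list[str]:
        return [f"seq{i:04d}" for i in range(self.n_sequences)]

    def donor_ids(self) -> list[str]:
        return [f"donor{i + 1}" for i in range(self.n_donors)]

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be >= 1")
        if self.n_tech_reps < 1:
            raise ConfigurationError("n_tech_reps must be >= 1")
        if not self.passages:
            raise ConfigurationError("passages must be non-empty")
        if self.n_mirnas > self.n_sequences:
            raise ConfigurationError("n_mirnas cannot exceed n_sequences")
        lo, hi = self.probe_reps_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                "probe_reps_range must be an inclusive range with 1 <= lo <= hi"
            )
        if self.n_negative_controls < 1:
            raise ConfigurationError("n_negative_controls must be >= 1")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ConfigurationError("expressed_fraction must lie in [0, 1]")
        if 2 * self.n_duplicate_pairs > self.n_sequences:
            raise ConfigurationError("n_duplicate_pairs too large for n_sequences")
        seq_ids = set(self.sequence_ids())
        for seq in self.passage_effects:
            if seq not in seq_ids:
                raise ConfigurationError(
                    f"passage_effects references unknown sequence {seq!r}"
                )
        for seq, shifts in self.passage_effects.items():
            for p in shifts:
                if p not in self.passages:
                    raise ConfigurationError(
                        f"passage_effects[{seq!r}] references unknown passage {p!r}"
                    )
        donors = set(self.donor_ids())
        for d, p in self.dropout_donors.items():
            if d not in donors:
                raise ConfigurationError(f"dropout_donors references unknown donor {d!r}")
            if p not in self.passages:
                raise ConfigurationError(
                    f"dropout_donors[{d!r}] references unknown passage {p!r}"
                )


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    #: per-sequence annotation: mirna_name, rna_class, baseline_log2, expressed
    annotations: pd.DataFrame
    #: sequences whose baseline exceeds the negative-control background cutoff
    true_detected: set[str]
    #: sequence -> {(late, early) -> log2 difference}, nonzero effects only
    true_de: dict[str, dict[tuple[str, str], float]]
    #: sequence -> log2 shift of the cancer cohort (nonzero only)
    true_cancer_de: dict[str, float]
    duplicate_pairs: list[tuple[str, str, float]]
    array_offsets: pd.Series
    donor_effects: pd.DataFrame


def _build_annotations(config: SimulationConfig, rng: np.random.Generator):
    """Assign miRNA names, duplicate pairs, rna_class and baselines."""
    seqs = config.sequence_ids()
    n = config.n_sequences
    mirnas = [f"mir{i + 1:04d}" for i in range(config.n_mirnas)]

    if config.duplicate_pairs is not None:
        pairs = list(config.duplicate_pairs)
    else:
        pairs = [
            (seqs[2 * i], seqs[2 * i + 1], config.duplicate_log2_offset)
            for i in range(config.n_duplicate_pairs)
        ]
    pair_seqs: dict[str, tuple[int, bool]] = {}
    for i, (long_s, short_s, _off) in enumerate(pairs):
        if long_s == short_s:
            raise ConfigurationError("duplicate pair must reference distinct sequences")
        pair_seqs[long_s] = (i, True)
        pair_seqs[short_s] = (i, False)

    mirna_of = {}
    next_mirna = len(pairs)
    for s in seqs:
        if s in pair_seqs:
            mirna_of[s] = mirnas[pair_seqs[s][0]]
        else:
            mirna_of[s] = mirnas[next_mirna % config.n_mirnas]
            next_mirna += 1

    # expressed set: all duplicate-pair members and all effect-carrying
    # sequences are expressed; the remainder is filled at random, and a
    # further slice is donor-variable (expressed in some donors only)
    n_expressed = int(round(config.expressed_fraction * n))
    forced = set(pair_seqs) | set(config.passage_effects)
    n_expressed = max(n_expressed, len(forced))
    free = [s for s in seqs if s not in forced]
    n_variable = min(int(round(config.variable_fraction * n)),
                     len(free) - (n_expressed - len(forced)))
    picked = rng.choice(len(free), size=n_expressed - len(forced) + n_variable,
                        replace=False)
    expressed = forced | {free[i] for i in picked[: n_expressed - len(forced)]}
    variable = {free[i] for i in picked[n_expressed - len(forced):]}

    base_lo, base_hi = config.baseline_log2_range
    bg_lo, bg_hi = config.background_log2_range
    var_lo, var_hi = config.variable_log2_range
    baseline = pd.Series(index=seqs, dtype=float)
    for s in seqs:
        if s in expressed:
            if config.baseline_tail_scale is not None:
                b = bg_hi + rng.exponential(config.baseline_tail_scale)
                baseline[s] = min(b, 10.0)
            else:
                baseline[s] = rng.uniform(base_lo, base_hi)
        elif s in variable:
            baseline[s] = rng.uniform(var_lo, var_hi)
        else:
            baseline[s] = rng.uniform(bg_lo, bg_hi)
    # effect carriers sit solidly above background yet at moderate intensity,
    # where technical cutoffs stay below study-magnitude effects
    for s in config.passage_effects:
        baseline[s] = rng.uniform(5.9, 6.3)
    # a duplicate pair shares one baseline high enough that both members
    # stay above background; the short member sits `off` below the long one
    for long_s, short_s, off in pairs:
        baseline[long_s] = rng.uniform(5.8 + off, 9.0)
        baseline[short_s] = baseline[long_s] - off

    # a few expressed sequences are annotated as tRNA/rRNA contaminants
    rna_class = pd.Series("miRNA", index=seqs, dtype=object)
    candidates = [s for s in sorted(expressed) if s not in pair_seqs
                  and s not in config.passage_effects]
    picked = candidates[: config.n_rrna_trna]
    for j, s in enumerate(picked):
        rna_class[s] = "tRNA" if j % 2 == 0 else "rRNA"

    ann = pd.DataFrame(
        {
            "mirna_name": [mirna_of[s] for s in seqs],
            "rna_class": rna_class,
            "baseline_log2": baseline,
            "expressed": [s in expressed for s in seqs],
            "component": ["expressed" if s in expressed
                          else "variable" if s in variable
                          else "background" for s in seqs],
            "donor_sd_multiplier": [
                config.variable_donor_multiplier if s in variable else 1.0
                for s in seqs
            ],
        },
        index=pd.Index(seqs, name="sequence_id"),
    )
    return ann, pairs


def simulate_experiment(config: SimulationConfig):
    """Generate one probe-level experiment.

    Returns ``(probe_table, sample_sheet, ground_truth)``.  The probe table is
    a long-format DataFrame with one row per (array, probe) — experimental
    probes carry ``probe_reps`` rows per sequence per array, and every array
    carries ``n_negative_controls`` negative-control rows.  Deterministic for
    a given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ann, pairs = _build_annotations(config, rng)
    seqs = config.sequence_ids()
    n_seq = config.n_sequences

    lo, hi = config.probe_reps_range
    probe_reps = rng.integers(lo, hi + 1, size=n_seq)

    # array roster: MSC donors x passages x technical reps, minus dropouts
    rows = []
    for d in config.donor_ids():
        last = config.dropout_donors.get(d)
        for p in config.passages:
            if last is not None and config.passages.index(p) > config.passages.index(last):
                continue
            for r in range(1, config.n_tech_reps + 1):
                rows.append((f"{d}_{p}_{r}", d, p, r, "MSC"))
    for c in config.cancer_samples:
        for r in range(1, config.cancer_reps + 1):
            rows.append((f"{c}_{r}", c, "NA", r, "cancer"))
    sheet = pd.DataFrame(
        rows, columns=["array_id", "donor_id", "passage_label",
                       "tech_rep_index", "cohort"],
    )

    n_arr = len(sheet)
    baseline = ann["baseline_log2"].to_numpy()

    pass_eff = np.zeros((n_seq, n_arr))
    seq_pos = {s: i for i, s in enumerate(seqs)}
    for s, shifts in config.passage_effects.items():
        for p, shift in shifts.items():
            cols = (sheet["passage_label"] == p).to_numpy()
            pass_eff[seq_pos[s], cols] += shift
    for s, shift in config.cancer_effects.items():
        cols = (sheet["cohort"] == "cancer").to_numpy()
        pass_eff[seq_pos[s], cols] += shift

    donors = list(dict.fromkeys(sheet["donor_id"]))
    donor_eff = pd.DataFrame(
        rng.normal(0.0, config.sigma_donor, size=(len(donors), n_seq))
        * ann["donor_sd_multiplier"].to_numpy()[None, :],
        index=donors, columns=seqs,
    )
    array_offsets = pd.Series(
        rng.normal(0.0, config.sigma_array, size=n_arr),
        index=sheet["array_id"].to_numpy(), name="array_offset",
    )
    noise_scale = 1.0 + config.sigma_vs_intensity_slope * np.clip(
        baseline - 6.0, 0.0, None
    )
    seq_array_noise = (
        rng.normal(0.0, config.sigma_seq_array, size=(n_seq, n_arr))
        * noise_scale[:, None]
    )

    donor_idx = [donors.index(d) for d in sheet["donor_id"]]
    cell_log2 = (
        baseline[:, None]
        + donor_eff.to_numpy()[donor_idx, :].T
        + pass_eff
        + array_offsets.to_numpy()[None, :]
        + seq_array_noise
    )

    if config.interaction_fraction > 0.0:
        # donor-specific passage trajectories for a slice of expressed
        # sequences: a per-(sequence, donor, passage) shift, zero at the
        # first passage so trajectories start from a common point
        n_inter = int(round(config.interaction_fraction * n_seq))
        candidates = [seq_pos[s] for s in ann.index
                      if ann.loc[s, "expressed"]
                      and s not in config.passage_effects][:n_inter]
        shifts = rng.normal(
            0.0, config.sigma_interaction,
            size=(len(candidates), len(donors), len(config.passages)),
        )
        shifts[:, :, 0] = 0.0
        p_idx = [config.passages.index(p) if p in config.passages else None
                 for p in sheet["passage_label"]]
        for a in range(n_arr):
            if p_idx[a] is None:
                continue
            cell_log2[candidates, a] += shifts[:, donor_idx[a], p_idx[a]]

    # expand to probe rows: same physical probe layout on every array
    seq_row_idx = np.repeat(np.arange(n_seq), probe_reps)  # per-array layout
    n_probe_rows = len(seq_row_idx)
    probe_ids = np.array(
        [f"{seqs[i]}_p{j + 1}"
         for i in range(n_seq) for j in range(probe_reps[i])]
    )

    tables = []
    negctl_ids = np.array(
        [f"negctl{i + 1:04d}" for i in range(config.n_negative_controls)]
    )
    for a in range(n_arr):
        arr_id = sheet["array_id"].iloc[a]
        log2 = cell_log2[seq_row_idx, a] + rng.normal(
            0.0, config.sigma_probe, size=n_probe_rows
        ) * noise_scale[seq_row_idx]
        neg_log2 = rng.normal(
            config.negctl_mean + config.outlier_arrays.get(arr_id, 0.0),
            config.negctl_sd, size=config.n_negative_controls,
        )
        tables.append(pd.DataFrame({
            "array_id": arr_id,
            "probe_id": np.concatenate([probe_ids, negctl_ids]),
            "sequence_id": np.concatenate(
                [np.array(seqs, dtype=object)[seq_row_idx], negctl_ids]
            ),
            "mirna_name": np.concatenate(
                [ann["mirna_name"].to_numpy()[seq_row_idx],
                 np.full(config.n_negative_controls, "", dtype=object)]
            ),
            "control_type": np.concatenate(
                [np.full(n_probe_rows, "experimental", dtype=object),
                 np.full(config.n_negative_controls, "negative", dtype=object)]
            ),
            "rna_class": np.concatenate(
                [ann["rna_class"].to_numpy()[seq_row_idx],
                 np.full(config.n_negative_controls, "unknown", dtype=object)]
            ),
            "raw_signal": np.exp2(np.concatenate([log2, neg_log2])),
        }))
    probes = pd.concat(tables, ignore_index=True)

    detection_cutoff = config.negctl_mean + config.negctl_sd
    true_detected = set(ann.index[ann["baseline_log2"] > detection_cutoff])

    true_de: dict[str, dict[tuple[str, str], float]] = {}
    for s, shifts in config.passage_effects.items():
        contrasts = {}
        labels = list(config.passages)
        for i, early in enumerate(labels):
            for late in labels[i + 1:]:
                d = shifts.get(late, 0.0) - shifts.get(early, 0.0)
                if d != 0.0:
                    contrasts[(late, early)] = d
        if contrasts:
            true_de[s] = contrasts

    truth = GroundTruth(
        annotations=ann,
        true_detected=true_detected,
        true_de=true_de,
        true_cancer_de={s: v for s, v in config.cancer_effects.items() if v != 0.0},
        duplicate_pairs=pairs,
        array_offsets=array_offsets,
        donor_effects=donor_eff,
    )
    return probes, sheet, truth


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration reproducing the study design end to end.

    8 MSC donors at P3/P5/P7 in triplicate with two early-dropout donors
    (21 donor/passage groups, 63 arrays), two elevated-background outlier
    arrays, two cancer samples in duplicate, 12 sequences carrying the
    reported passage-effect magnitudes and 41 one-base duplicate pairs with
    a 0.74 log2 long-over-short offset.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.dropout_donors = dict(cfg.dropout_donors) or {
        "donor7": "P5",   # stopped before P7
        "donor8": "P3",   # only reached P3
    }
    if not cfg.outlier_arrays:
        cfg.outlier_arrays = {"donor1_P7_1": 3.0, "donor3_P5_1": 3.0}
    if not cfg.cancer_samples:
        cfg.cancer_samples = ("NT2", "UHRR")
    seqs = cfg.sequence_ids()
    if not cfg.passage_effects:
        # effect carriers start after the duplicate-pair block
        start = 2 * cfg.n_duplicate_pairs
        effects = {}
        for i, (f7, f5) in enumerate(zip(STUDY_P7_FOLDS, STUDY_P5_FOLDS)):
            s = seqs[start + i]
            shifts = {"P7": _signed_fold_to_log2(f7)}
            if f5 is not None:
                shifts["P5"] = _signed_fold_to_log2(f5)
            effects[s] = shifts
        cfg.passage_effects = effects
    if not cfg.cancer_effects and cfg.cancer_samples:
        rng = np.random.default_rng(seed + 104729)
        start = 2 * cfg.n_duplicate_pairs + len(STUDY_P7_FOLDS)
        shifts = rng.uniform(0.4, np.log2(7.16), size=60) * rng.choice(
            [-1.0, 1.0], size=60
        )
        cfg.cancer_effects = {
            seqs[start + i]: float(shifts[i]) for i in range(60)
        }
    return cfg


# ---------------------------------------------------------------------------
# RT-qPCR simulation


@dataclass
class QpcrSimConfig:
    """Design of a synthetic RT-qPCR confirmation experiment.

    Two matched MSC sets (lines measured at an early and a late passage),
    optional non-MSC cohorts, 5 reference targets normalized by geometric
    mean, and positive/negative run controls.
    """

    targets: tuple[str, ...] = tuple(f"miR-t{i + 1:02d}" for i in range(30))
    references: tuple[str, ...] = REFERENCE_TARGETS
    set1_lines: tuple[str, ...] = tuple(f"line1_{i + 1}" for i in range(6))
    set1_passages: tuple[str, str] = ("P3", "P7")
    set2_lines: tuple[str, ...] = tuple(f"line2_{i + 1}" for i in range(7))
    set2_passages: tuple[str, str] = ("P4", "P8")
    mesoderm_lines: tuple[str, ...] = ()
    cancer_lines: tuple[str, ...] = ()
    #: target -> baseline Cq (targets with baseline >= undetected_cq never amplify)
    baseline_cq: dict[str, float] = field(default_factory=dict)
    reference_cq: float = 21.0
    #: (set_name, target) -> Cq shift at the late passage (negative = upregulated)
    passage_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    #: target -> Cq shift in non-MSC cohorts
    cohort_shifts: dict[str, float] = field(default_factory=dict)
    sigma_well: float = 0.15
    sample_offset_sd: float = 0.5
    n_well_reps: int = 3
    undetected_cq: float = 35.0
    #: "cq40" emits undetected wells at Cq 40; "missing" drops the rows
    undetected_mode: str = "cq40"
    seed: int = 0

    def validate(self) -> None:
        for r in self.references:
            if r in self.targets:
                raise ConfigurationError(
                    f"reference {r!r} must not also be an assayed target"
                )
        if self.n_well_reps < 1:
            raise ConfigurationError("n_well_reps must be >= 1")
        if self.undetected_mode not in ("cq40", "missing"):
            raise ConfigurationError("undetected_mode must be 'cq40' or 'missing'")
        for (set_name, t) in self.passage_shifts:
            if set_name not in ("set1", "set2"):
                raise ConfigurationError(f"unknown MSC set {set_name!r}")
            if t not in self.targets:
                raise ConfigurationError(
                    f"passage_shifts references unknown target {t!r}"
                )


@dataclass
class QpcrGroundTruth:
    """Configured Cq baselines and true folds per (set, target)."""

    baseline_cq: dict[str, float]
    #: (set_name, target) -> true late/early fold on the abundance scale (signed)
    true_folds: dict[tuple[str, str], float]


def simulate_qpcr(config: QpcrSimConfig):
    """Generate a long-format Cq plate and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    baseline = dict(config.baseline_cq)
    for t in config.targets:
        if t not in baseline:
            baseline[t] = float(rng.uniform(24.0, 31.0))

    samples = []  # (sample_id, cohort, passage, set_name, line)
    for line in config.set1_lines:
        for p in config.set1_passages:
            samples.append((f"{line}_{p}", "MSC_set1", p, "set1", line))
    for line in config.set2_lines:
        for p in config.set2_passages:
            samples.append((f"{line}_{p}", "MSC_set2", p, "set2", line))
    for line in config.mesoderm_lines:
        samples.append((line, "mesoderm", "NA", None, line))
    for line in config.cancer_lines:
        samples.append((line, "cancer", "NA", None, line))

    rows = []
    for sample_id, cohort, passage, set_name, _line in samples:
        offset = rng.normal(0.0, config.sample_offset_sd)
        late = (set_name == "set1" and passage == config.set1_passages[1]) or (
            set_name == "set2" and passage == config.set2_passages[1]
        )
        for t in list(config.references) + list(config.targets):
            is_ref = t in config.references
            cq0 = config.reference_cq if is_ref else baseline[t]
            shift = 0.0
            if not is_ref:
                if late and (set_name, t) in config.passage_shifts:
                    shift += config.passage_shifts[(set_name, t)]
                if cohort in ("mesoderm", "cancer"):
                    shift += config.cohort_shifts.get(t, 0.0)
            for w in range(1, config.n_well_reps + 1):
                cq = cq0 + shift + offset + rng.normal(0.0, config.sigma_well)
                undet = cq0 + shift >= config.undetected_cq
                if undet and config.undetected_mode == "missing":
                    continue
                rows.append({
                    "sample_id": sample_id,
                    "cohort": cohort,
                    "passage_label": passage,
                    "target_id": t,
                    "is_reference": is_ref,
                    "control_role": "none",
                    "well_rep_index": w,
                    "cq": 40.0 if undet else float(np.clip(cq, 1.0, 45.0)),
                })
        # run controls: PPC (positive PCR control) and miRTC (RT control)
        for role, cq0 in (("PPC", 19.0), ("miRTC", 22.0)):
            for w in range(1, config.n_well_reps + 1):
                rows.append({
                    "sample_id": sample_id, "cohort": cohort,
                    "passage_label": passage, "target_id": role,
                    "is_reference": False, "control_role": role,
                    "well_rep_index": w,
                    "cq": float(cq0 + rng.normal(0.0, config.sigma_well)),
                })
    plate = pd.DataFrame(rows)

    true_folds = {}
    for (set_name, t), dcq in config.passage_shifts.items():
        # a -dCq at late passage means 2**dCq-fold up on the abundance scale
        d = -dcq
        true_folds[(set_name, t)] = float(2.0 ** d if d >= 0 else -(2.0 ** -d))
    return plate, QpcrGroundTruth(baseline_cq=baseline, true_folds=true_folds)


def study_qpcr_config(seed: int = 0, **overrides) -> QpcrSimConfig:
    """qPCR design matching the confirmation arm of the study.

    30 assayed miRNAs; in MSC set 1 two targets are upregulated at the late
    passage by 1.54- and 1.71-fold, and in set 2 by 1.59- and 1.35-fold;
    mesoderm and cancer cohorts are included for the cross-cohort contrasts.
    """
    cfg = QpcrSimConfig(seed=seed, **overrides)
    if not cfg.mesoderm_lines:
        cfg.mesoderm_lines = ("fibro1", "fibro2", "osteo1", "chondro1")
    if not cfg.cancer_lines:
        cfg.cancer_lines = ("NT2", "OVCAR5", "SKOV3", "HS766T")
    if not cfg.passage_shifts:
        mir572, mir638 = cfg.targets[0], cfg.targets[1]
        cfg.passage_shifts = {
            ("set1", mir572): -np.log2(1.54),
            ("set1", mir638): -np.log2(1.71),
            ("set2", mir572): -np.log2(1.59),
            ("set2", mir638): -np.log2(1.35),
        }
    if not cfg.baseline_cq:
        rng = np.random.default_rng(seed + 7919)
        cfg.baseline_cq = {
            t: float(rng.uniform(24.0, 31.0)) for t in cfg.targets
        }
        # a few targets sit beyond the detection limit on this platform
        for t in cfg.targets[-3:]:
            cfg.baseline_cq[t] = 37.0
    return cfg
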