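"""End-to-end network detection: model and results objects, cohort harness.

``RSNDetectionModel`` bundles a recording, its montage/leadfield and a
template set; ``fit()`` runs preprocessing, source localization, power
envelopes, spatial ICA and template matching, returning an
``RSNDetectionResults`` with the detected maps, assignment quality and
diagnostics.  The cohort functions generate synthetic subjects and run the
montage-density / head-model / inverse-method comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import Montage, NetworkMap, Recording
from .evaluate import ComparisonResult, run_factor_comparison, spatial_correlation
from .forward import (HeadModel, Leadfield, SourceSpace, build_source_grid,
                      compute_leadfield, headmodel_variants, subsample_montage)
from .inverse import InverseConfig, make_inverse_operator
from .netdetect import (ICResult, RSNAssignment, TemplateSet,
                        compute_power_envelopes_from_operator,
                        estimate_num_ics_mdl, match_templates, run_spatial_ica)
from .preprocess import PreprocessConfig, average_reference, bandpass_filter, preprocess
from .synthdata import NoiseSpec, make_montage, simulate_subject


@dataclass
class PipelineConfig:
    """Every tunable of the detection chain, in processing order."""

    preprocess: str = "light"        # "full" | "light" (band-pass + avg ref) | "none"
    preprocess_cfg: PreprocessConfig = field(default_factory=PreprocessConfig)
    inverse_method: str = "eloreta"
    inverse_cfg: InverseConfig | None = None
    window: float = 1.0              # s, envelope window
    step: float = 1.0                # s, envelope step
    k: object = "auto"               # "auto" (MDL, floored at template count) or int
    n_runs: int = 10                 # FastICA restarts
    seed: int = 0

    def describe(self) -> dict:
        """Flat settings dict used to verify single-factor experiments."""
        return {
            "preprocess": self.preprocess,
            "inverse": self.inverse_method,
            "window": self.window,
            "step": self.step,
            "k": self.k,
            "n_runs": self.n_runs,
        }


class RSNDetectionModel:
    """Resting-state-network detector for one recording.

    Parameters
    ----------
    recording : Recording
        Raw or preprocessed multichannel recording.
    montage : Montage
        Channel positions matching the recording.
    leadfield : Leadfield
        Forward gain for the recording's EEG channels.
    templates : TemplateSet
        Labeled network templates on the same source grid.
    config : PipelineConfig
    """

    def __init__(self, recording: Recording, montage: Montage,
                 leadfield: Leadfield, templates: TemplateSet,
                 config: PipelineConfig | None = None, operator=None):
        if len(recording.eeg_indices) != leadfield.n_channels:
            raise ValueError("recording EEG channel count does not match leadfield")
        self.recording = recording
        self.montage = montage
        self.leadfield = leadfield
        self.templates = templates
        self.config = config or PipelineConfig()
        # optional precomputed inverse operator (e.g. eLORETA, which does not
        # depend on the data and can be shared across recordings)
        if operator is not None and operator.method != self.config.inverse_method:
            raise ValueError("precomputed operator method does not match config")
        self.operator = operator

    def _clean(self, rec: Recording) -> Recording:
        cfg = self.config
        if cfg.preprocess == "full":
            clean, _, _ = preprocess(rec, self.montage, cfg.preprocess_cfg)
            return clean
        if cfg.preprocess == "light":
            clean = bandpass_filter(rec, cfg.preprocess_cfg.low,
                                    cfg.preprocess_cfg.high)
            return average_reference(clean)
        return rec

    def _detect(self, rec: Recording):
        cfg = self.config
        clean = self._clean(rec)
        op = self.operator
        if op is None:
            op = make_inverse_operator(cfg.inverse_method, self.leadfield,
                                       rec=clean, cfg=cfg.inverse_cfg)
        env = compute_power_envelopes_from_operator(clean, op, cfg.window, cfg.step)
        if cfg.k == "auto":
            k = estimate_num_ics_mdl(env)
            k = max(k, len(self.templates.names))
            k = min(k, min(env.n_sources, env.n_windows) - 1)
        else:
            k = int(cfg.k)
        ics = run_spatial_ica(env, k, n_runs=cfg.n_runs, seed=cfg.seed)
        assignment = match_templates(ics, self.templates)
        maps = {name: NetworkMap(values=ics.maps[:, idx], name=name)
                for name, (idx, _) in assignment.assignments.items()}
        return clean, op, env, ics, assignment, maps

    def fit(self) -> "RSNDetectionResults":
        clean, op, env, ics, assignment, maps = self._detect(self.recording)
        return RSNDetectionResults(model=self, operator=op, envelope=env,
                                   ic_result=ics, assignment=assignment,
                                   maps=maps)

    def detect_on(self, rec: Recording) -> dict:
        """Run the identical chain on another recording (e.g. one half)."""
        return self._detect(rec)[5]


@dataclass
class RSNDetectionResults:
    """Fitted network detection: maps, match quality, and diagnostics."""

    model: RSNDetectionModel
    operator: object
    envelope: object
    ic_result: ICResult
    assignment: RSNAssignment
    maps: dict

    @property
    def k(self) -> int:
        return self.ic_result.k

    def correlations_with(self, truth: dict) -> dict:
        """Spatial correlation of each matched map with a reference map."""
        return {name: spatial_correlation(self.maps[name], truth[name])
                for name in self.maps if name in truth}

    def split_half(self) -> dict:
        """Re-detect on each half of the recording; correlate per network."""
        from .evaluate import split_half as _sh
        return _sh(self.model.recording, self.model.detect_on,
                   self.model.templates)

    def summary(self) -> str:
        lines = ["Resting-state network detection",
                 "=" * 47,
                 f"  inverse method : {self.model.config.inverse_method}",
                 f"  components (k) : {self.k}",
                 f"  envelope       : {self.envelope.n_windows} windows of "
                 f"{self.envelope.window:g} s",
                 f"  ICA runs       : {len(self.ic_result.objectives)} "
                 f"(best run {self.ic_result.best_run})",
                 "-" * 47,
                 f"  {'network':<10}{'IC':>4}{'match r':>10}"]
        for name, (idx, r) in sorted(self.assignment.assignments.items()):
            lines.append(f"  {name:<10}{idx:>4}{r:>10.3f}")
        if self.assignment.unmatched_ics:
            lines.append(f"  unmatched ICs  : {self.assignment.unmatched_ics}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# synthetic cohort harness


@dataclass
class CohortConfig:
    """Shared study conditions for a synthetic comparison cohort."""

    n_subjects: int = 12
    n_electrodes: int = 256
    fs: float = 1000.0
    duration: float = 300.0
    k_networks: int = 4
    spacing: float = 0.006
    head: HeadModel = field(default_factory=HeadModel.four_shell)
    seed: int = 0
    snr: float = 4.0
    artifacts: bool = False
    n_runs: int = 10


def _subject_maps(rec, montage, leadfield, templates, method="eloreta",
                  k="auto", n_runs=10, seed=0, operator=None):
    cfg = PipelineConfig(preprocess="light", inverse_method=method, k=k,
                         n_runs=n_runs, seed=seed)
    model = RSNDetectionModel(rec, montage, leadfield, templates, cfg,
                              operator=operator)
    res = model.fit()
    return res.maps, cfg.describe()


def _subsample_leadfield(lf: Leadfield, keep: np.ndarray) -> Leadfield:
    gain = lf.gain[keep] - lf.gain[keep].mean(axis=0, keepdims=True)
    return Leadfield(gain=gain, labels=[lf.labels[i] for i in keep],
                     reference="average", head_label=lf.head_label,
                     spacing=lf.spacing, truncation_order=lf.truncation_order)


def run_cohort_experiment(factor: str, cohort: CohortConfig,
                          levels=None) -> ComparisonResult:
    """Montage / head-model / inverse comparison on a synthetic cohort.

    Each synthetic subject is simulated once at the full montage under the
    reference head model; only the stated factor is varied when re-running
    detection, so differences across levels isolate that factor.
    """
    if factor == "montage":
        levels = list(levels or [cohort.n_electrodes, 128, 64, 32])
        reference = cohort.n_electrodes
    elif factor == "headmodel":
        levels = list(levels or ["reference", "merged", "averaged"])
        reference = "reference"
    elif factor == "inverse":
        levels = list(levels or ["eloreta", "sloreta", "mne", "lcmv"])
        reference = "eloreta"
    else:
        raise ValueError("factor must be montage, headmodel or inverse")

    montage = make_montage(cohort.n_electrodes, head_radius=cohort.head.scalp_radius)
    space = build_source_grid(cohort.head, spacing=cohort.spacing)
    lf_ref = compute_leadfield(montage, cohort.head, space)

    # per-level fixed assets: leadfield, montage-selection, cached eLORETA
    # operator (data-independent, shared across subjects)
    from .inverse import compute_eloreta_operator
    level_assets = {}
    variants = headmodel_variants() if factor == "headmodel" else None
    for lev in levels:
        lf_l = lf_ref
        method = "eloreta"
        if factor == "headmodel" and lev != "reference":
            lf_l = compute_leadfield(montage, variants[lev], space)
        elif factor == "inverse":
            method = lev
        level_assets[lev] = {"lf": lf_l, "method": method}
    # montage subsampling: determine the channel selection once
    if factor == "montage":
        probe = Recording(data=np.zeros((montage.n_channels, 10)), fs=cohort.fs,
                          labels=list(montage.labels), kinds=list(montage.kinds))
        for lev in levels:
            if lev == cohort.n_electrodes:
                level_assets[lev]["montage"] = montage
                continue
            _, mont_l = subsample_montage(probe, montage, lev)
            keep = np.array([lf_ref.labels.index(mont_l.labels[i])
                             for i in mont_l.eeg_indices])
            level_assets[lev]["montage"] = mont_l
            level_assets[lev]["keep"] = keep
            level_assets[lev]["lf"] = _subsample_leadfield(lf_ref, keep)
    for lev, assets in level_assets.items():
        if assets["method"] == "eloreta":
            assets["operator"] = compute_eloreta_operator(assets["lf"])

    subject_runs = []
    for s in range(cohort.n_subjects):
        seed = cohort.seed + 1000 * (s + 1)
        rec, truth_maps, spec = simulate_subject(
            space, lf_ref, montage, seed=seed, k=cohort.k_networks,
            duration=cohort.duration, fs=cohort.fs,
            noise=NoiseSpec(sensor_snr=cohort.snr, seed=seed),
            artifacts=cohort.artifacts)
        templates = TemplateSet.from_network_maps(truth_maps)
        truth = {m.name: m for m in truth_maps}
        run = {"__truth__": truth, "__config__": {}}
        for lev in levels:
            assets = level_assets[lev]
            rec_l, mont_l = rec, montage
            if factor == "montage" and lev != cohort.n_electrodes:
                sel = list(assets["keep"]) + [rec.aux_index(k)
                                              for k in ("hEOG", "vEOG", "EMG")]
                rec_l = rec.select_channels(sel)
                mont_l = assets["montage"]
            maps, desc = _subject_maps(rec_l, mont_l, assets["lf"], templates,
                                       method=assets["method"],
                                       k=cohort.k_networks,
                                       n_runs=cohort.n_runs, seed=seed,
                                       operator=assets.get("operator"))
            desc[factor] = lev
            run[lev] = maps
            run["__config__"][lev] = desc
        subject_runs.append(run)
    return run_factor_comparison(subject_runs, factor, levels, reference)
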