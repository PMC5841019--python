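"""Detection-performance statistics and comparison experiments.

Spatial Pearson correlations between network maps, split-half
reproducibility, one-sample sign-flip permutation tests with
threshold-free cluster enhancement (TFCE) and max-statistic FWER
correction, repeated-measures ANOVA on Fisher-transformed correlations,
and the montage-density / head-model / inverse-method comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .containers import NetworkMap, Recording
from .forward import SourceSpace


def spatial_correlation(a, b) -> float:
    """Pearson correlation between two per-source maps."""
    av = a.values if isinstance(a, NetworkMap) else np.asarray(a, float).ravel()
    bv = b.values if isinstance(b, NetworkMap) else np.asarray(b, float).ravel()
    if av.shape != bv.shape:
        raise ValueError("maps live on different source spaces")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance map: correlation undefined")
    return float(np.corrcoef(av, bv)[0, 1])


def cross_correlation_matrix(A: list, B: list) -> np.ndarray:
    """|A| x |B| matrix of spatial correlations."""
    out = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            out[i, j] = spatial_correlation(a, b)
    return out


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def tfce_transform(values: np.ndarray, space: SourceSpace, H: float = 2.0,
                   E: float = 0.5, dh: float | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement on the source lattice.

    For each source, integrates extent(h)^E * h^H dh over thresholds h from
    0 to the map maximum, where extent(h) is the size of the source's
    6-connected suprathreshold cluster at height h.  Only positive values
    are enhanced; non-positive sources map to 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if space.grid_ijk is None:
        raise ValueError("source space lacks lattice indices")
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        return np.zeros_like(v)
    if dh is None:
        dh = vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    vol = np.zeros(space.vol_shape)
    ijk = tuple(space.grid_ijk.T)
    vol[ijk] = v
    out = np.zeros_like(v)
    h = dh
    while h <= vmax + 1e-12:
        mask = vol >= h
        labels, n = ndimage.label(mask, structure=_STRUCT6)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        lab_src = labels[ijk]
        above = lab_src > 0
        out[above] += sizes[lab_src[above]] ** E * h ** H * dh
        h += dh
    return out


@dataclass
class GroupStatMap:
    t: np.ndarray
    tfce: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    n_subjects: int
    n_permutations: int
    exhaustive: bool = False


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    n = maps.shape[0]
    return mean / np.maximum(sd / np.sqrt(n), 1e-300)


def group_map_permutation(maps: np.ndarray, space: SourceSpace,
                          n_perm: int = 5000, alpha: float = 0.01,
                          seed: int = 0, H: float = 2.0, E: float = 0.5,
                          dh: float | None = None) -> GroupStatMap:
    """One-sample sign-flip permutation test with TFCE and FWER correction.

    The statistic is the TFCE-enhanced one-sample t map; corrected p-values
    come from the permutation distribution of the maximum TFCE statistic.
    When n_perm >= 2^n_subjects all sign patterns are enumerated exactly.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub, n_src = maps.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects")
    t_obs = _one_sample_t(maps)
    dh_obs = dh if dh is not None else max(t_obs.max(initial=0.0), 1e-12) / 100.0
    tfce_obs = tfce_transform(t_obs, space, H=H, E=E, dh=dh_obs)

    exhaustive = n_perm >= 2 ** n_sub
    if exhaustive:
        signs = np.array([[1 if (i >> b) & 1 else -1 for b in range(n_sub)]
                          for i in range(2 ** n_sub)], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    max_null = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        t_p = _one_sample_t(maps * s[:, None])
        max_null[i] = tfce_transform(t_p, space, H=H, E=E, dh=dh_obs).max(initial=0.0)
    if exhaustive:
        p = (max_null[None, :] >= tfce_obs[:, None] - 1e-12).mean(axis=1)
    else:
        p = (1.0 + (max_null[None, :] >= tfce_obs[:, None] - 1e-12).sum(axis=1)) \
            / (signs.shape[0] + 1.0)
    return GroupStatMap(t=t_obs, tfce=tfce_obs, p=p, mask=p < alpha,
                        n_subjects=n_sub, n_permutations=signs.shape[0],
                        exhaustive=exhaustive)


def fisher_rm_anova(r_table: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on Fisher-z-transformed correlations.

    Rows are subjects, columns are factor levels.  Returns (F, p) with
    (levels-1, (levels-1)(subjects-1)) degrees of freedom.
    """
    r = np.asarray(r_table, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("need subjects x levels with at least 2 levels")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 entries give infinite Fisher z")
    z = np.arctanh(r)
    n_sub, n_lev = z.shape
    grand = z.mean()
    ss_level = n_sub * ((z.mean(axis=0) - grand) ** 2).sum()
    ss_subject = n_lev * ((z.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((z - grand) ** 2).sum()
    ss_error = ss_total - ss_level - ss_subject
    df1 = n_lev - 1
    df2 = (n_lev - 1) * (n_sub - 1)
    ms_level = ss_level / df1
    ms_error = ss_error / df2
    if ms_error <= 0:
        return 0.0 if ms_level == 0 else np.inf, 1.0 if ms_level == 0 else 0.0
    F = ms_level / ms_error
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def split_half(rec: Recording, detect, templates) -> dict:
    """Split-half reproducibility of detected networks.

    ``detect(recording) -> {name: NetworkMap}`` is the full detection
    pipeline (preprocessed recording to matched network maps).  The
    recording is split into two equal disjoint segments covering it
    exactly; networks are detected independently in each and correlated
    pairwise per template name.
    """
    half = rec.duration / 2.0
    first = rec.crop(0.0, half)
    second = rec.crop(half, rec.duration)
    maps1 = detect(first)
    maps2 = detect(second)
    out = {}
    for name in templates.names:
        if name in maps1 and name in maps2:
            out[name] = spatial_correlation(maps1[name], maps2[name])
    return out


@dataclass
class ComparisonResult:
    factor: str
    levels: list
    reference_level: object
    # (subjects, levels, networks) spatial correlation with the
    # reference-level maps and with the ground-truth maps
    corr_vs_reference: np.ndarray
    corr_vs_truth: np.ndarray
    network_names: list
    anova_F: float
    anova_p: float
    level_configs: dict = field(default_factory=dict)

    def level_means_vs_truth(self) -> np.ndarray:
        return np.nanmean(self.corr_vs_truth, axis=(0, 2))

    def level_means_vs_reference(self) -> np.ndarray:
        return np.nanmean(self.corr_vs_reference, axis=(0, 2))


def run_factor_comparison(subject_runs, factor: str, levels: list,
                          reference_level) -> ComparisonResult:
    """Assemble a factor-comparison experiment from per-subject level runs.

    ``subject_runs`` is a list (one entry per subject) of dicts
    ``level -> {name: NetworkMap}`` plus a parallel ground-truth dict per
    subject under the key "__truth__".  Only the stated factor may vary
    across levels; the caller guarantees every other pipeline setting is
    shared (checked via the optional "__config__" hashes when present).
    The ANOVA is computed on Fisher-z per-subject mean correlations versus
    the reference level, excluding the reference level itself.
    """
    if reference_level not in levels:
        raise ValueError("reference level must be among the levels")
    n_sub = len(subject_runs)
    names = None
    configs = {}
    for run in subject_runs:
        cfgs = run.get("__config__", {})
        for lev, c in cfgs.items():
            base = {k: v for k, v in c.items() if k != factor}
            if lev in configs and configs[lev] != base:
                raise ValueError("non-factor settings differ across subjects")
            configs.setdefault(lev, base)
    if len({tuple(sorted(c.items())) for c in configs.values()}) > 1:
        raise ValueError(f"settings other than {factor!r} differ across levels")
    ref_names = sorted(subject_runs[0][reference_level].keys())
    names = ref_names
    n_net = len(names)
    corr_ref = np.full((n_sub, len(levels), n_net), np.nan)
    corr_truth = np.full((n_sub, len(levels), n_net), np.nan)
    for s, run in enumerate(subject_runs):
        truth = run.get("__truth__", {})
        ref_maps = run[reference_level]
        for li, lev in enumerate(levels):
            maps = run[lev]
            for ni, name in enumerate(names):
                if name not in maps:
                    continue
                if name in ref_maps:
                    corr_ref[s, li, ni] = spatial_correlation(maps[name],
                                                              ref_maps[name])
                if name in truth:
                    corr_truth[s, li, ni] = spatial_correlation(maps[name],
                                                                truth[name])
    non_ref = [li for li, lev in enumerate(levels) if lev != reference_level]
    r_table = np.nanmean(corr_ref[:, non_ref, :], axis=2)
    r_table = np.clip(r_table, -0.999999, 0.999999)
    F, p = fisher_rm_anova(r_table)
    return ComparisonResult(factor=factor, levels=list(levels),
                            reference_level=reference_level,
                            corr_vs_reference=corr_ref,
                            corr_vs_truth=corr_truth,
                            network_names=names, anova_F=F, anova_p=p,
                            level_configs=configs)
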