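"""Synthetic self-self baseline arrays and spike-in differential expression.

The generator stands in for a real set of self-self incubations (the
same plasma sample in both channels on every array): any nonzero M is
pure technical bias.  It emulates the features of such data that matter
for normalisation benchmarking:

* per-antibody average log2 intensities A from a log-normal distribution
  (skewed, spanning roughly 5-18 log2 units at the defaults);
* a smooth nonlinear intensity-dependent dye bias shared by all arrays
  (polynomial in scaled A);
* array-to-array variation: a constant M offset per array plus a random
  smooth intensity-dependent curve per array (without the latter, every
  bias would cancel in group contrasts and non-normalised data would
  look artificially well-behaved);
* duplicate spots per antibody with correlated M noise.

Differential expression is spiked in by shifting the M-values of the
'tumour' arrays for a randomly drawn set of antibodies by +/- the
absolute value of truncated-normal draws; A is left unchanged and the
channel intensities are recomputed as cy5 = 2^(A + M/2),
cy3 = 2^(A - M/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arraydata import ArraySet, ProbeLayout, TwoColourArray, intensities_from_ma

__all__ = [
    "BaselineModel",
    "Scenario",
    "SimulatedDataset",
    "generate_baseline",
    "spike_in",
    "scenario_grid",
    "sample_truncated_normal",
]

# scaling of A used by the bias polynomials: t = (A - 10) / 2.5
_A_CENTER = 10.0
_A_SCALE = 2.5


@dataclass(frozen=True)
class BaselineModel:
    """Parameters of the synthetic self-self baseline.

    ``a_meanlog``/``a_sdlog`` parameterise the log-normal A-value
    distribution (natural-log scale of the log2-intensity A).
    ``dye_bias`` holds polynomial coefficients (highest degree first)
    in t = (A − 10)/2.5 for the shared bias curve.  ``sd_curve`` is the
    standard deviation of the per-array random linear/quadratic bias
    coefficients in t; ``sd_array`` the per-array constant M offset sd;
    ``sd_noise`` the per-spot M noise sd; ``rho_dup`` the duplicate-spot
    noise correlation; ``a_jitter_sd`` the per-spot jitter of A around
    the antibody value.
    """

    n_arrays: int = 20
    n_antibodies: int = 810
    duplicates: int = 2
    a_meanlog: float = 2.30
    a_sdlog: float = 0.25
    dye_bias: tuple = (0.03, -0.10, -0.08, 0.25)
    sd_noise: float = 0.08
    sd_array: float = 0.05
    sd_curve: float = 0.50
    rho_dup: float = 0.6
    a_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.sd_noise, self.sd_array, self.sd_curve, self.a_jitter_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.rho_dup <= 1.0):
            raise ValueError("rho_dup must be in [0, 1]")
        if self.n_arrays < 2 or self.n_antibodies < 1 or self.duplicates < 1:
            raise ValueError("counts must be positive (>= 2 arrays)")

    @property
    def n_probes(self) -> int:
        return self.n_antibodies * self.duplicates


@dataclass(frozen=True)
class Scenario:
    """One spike-in scenario of the simulation study.

    ``prop_de`` is the fraction of antibodies differentially expressed;
    ``asym`` the fraction of those that are upregulated (0.5 symmetric,
    1.0 fully asymmetric); shifts are drawn from N(shift_mean,
    shift_sd^2) left-truncated at zero.
    """

    prop_de: float
    asym: float
    shift_mean: float = 0.1
    shift_sd: float = 0.1
    n_runs: int = 100
    name: str = ""

    def __post_init__(self):
        if not (0.0 <= self.prop_de <= 1.0):
            raise ValueError("prop_de must be in [0, 1]")
        if not (0.5 <= self.asym <= 1.0):
            raise ValueError("asym must be in [0.5, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not self.name:
            kind = "sym" if self.asym == 0.5 else "asym"
            object.__setattr__(self, "name", f"{kind}_{int(round(100 * self.prop_de))}")


@dataclass
class SimulatedDataset:
    """Spiked dataset: labelled arrays plus the per-antibody truth."""

    arrays: ArraySet
    truth_de: np.ndarray  # bool per antibody
    truth_direction: np.ndarray  # +1 / -1 / 0 per antibody
    truth_shift: np.ndarray  # shift magnitude per antibody (0 if not DE)
    scenario: Scenario
    run_seed: int

    @property
    def antibody_ids(self) -> np.ndarray:
        groups = self.arrays.layout.duplicate_group.astype(str)
        _, first = np.unique(groups, return_index=True)
        return groups[np.sort(first)]


def _bias_curve(coef, a: np.ndarray) -> np.ndarray:
    t = (np.asarray(a, float) - _A_CENTER) / _A_SCALE
    return np.polyval(np.asarray(coef, float), t)


def sample_truncated_normal(mean, sd, size, rng) -> np.ndarray:
    """Draws from N(mean, sd^2) left-truncated at zero (equivalently the
    absolute value convention of the spike-in scheme)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _make_layout(n_antibodies: int, duplicates: int) -> ProbeLayout:
    width = len(str(n_antibodies))
    ids = np.repeat(
        np.array([f"ab{g + 1:0{width}d}" for g in range(n_antibodies)], dtype=object),
        duplicates,
    )
    return ProbeLayout(antibody_id=ids, duplicate_group=ids.copy())


def generate_baseline(model: BaselineModel = BaselineModel(), rng=None) -> ArraySet:
    """Generate the self-self baseline arrays (no true DE, no labels).

    Identical seeds give bit-identical data.
    """
    rng = np.random.default_rng(model.seed if rng is None else rng)
    layout = _make_layout(model.n_antibodies, model.duplicates)
    a_ab = np.exp(rng.normal(model.a_meanlog, model.a_sdlog, model.n_antibodies))
    a_spots = np.repeat(a_ab, model.duplicates)

    arrays = []
    for _j in range(model.n_arrays):
        a = a_spots + rng.normal(0.0, model.a_jitter_sd, model.n_probes)
        t = (a - _A_CENTER) / _A_SCALE
        curve = _bias_curve(model.dye_bias, a)
        c1, c2 = rng.normal(0.0, model.sd_curve, 2)
        curve = curve + c1 * t + c2 * (t * t - 1.0)
        offset = rng.normal(0.0, model.sd_array) if model.sd_array > 0 else 0.0
        shared = rng.normal(0.0, 1.0, model.n_antibodies)
        own = rng.normal(0.0, 1.0, model.n_probes)
        noise = model.sd_noise * (
            np.sqrt(model.rho_dup) * np.repeat(shared, model.duplicates)
            + np.sqrt(1.0 - model.rho_dup) * own
        )
        m = curve + offset + noise
        cy5, cy3 = intensities_from_ma(m, a)
        arrays.append(
            TwoColourArray(layout=layout, cy5=cy5, cy3=cy3,
                           provenance={"simulated": True, "self_self": True})
        )
    return ArraySet(arrays=arrays)


def spike_in(baseline: ArraySet, scenario: Scenario, run_seed: int) -> SimulatedDataset:
    """Assign groups and spike differential expression into a baseline.

    Arrays are randomly split into balanced 'tumour'/'control' groups.
    DE antibodies are drawn without replacement; each receives one shift
    magnitude (truncated normal) applied with its direction to the
    M-values of both duplicate spots on every tumour array.  A-values
    are unchanged; intensities are recomputed from (M, A).
    """
    rng = np.random.default_rng(run_seed)
    n_arrays = baseline.n_arrays
    n_tumour = n_arrays // 2
    order = rng.permutation(n_arrays)
    is_tumour = np.zeros(n_arrays, dtype=bool)
    is_tumour[order[:n_tumour]] = True
    labels = ["tumour" if t else "control" for t in is_tumour]

    groups = baseline.layout.duplicate_group.astype(str)
    uniq, first = np.unique(groups, return_index=True)
    ab_order = np.argsort(first)
    antibodies = uniq[ab_order]
    n_ab = antibodies.size
    n_de = int(round(scenario.prop_de * n_ab))
    truth_de = np.zeros(n_ab, dtype=bool)
    truth_dir = np.zeros(n_ab, dtype=int)
    truth_shift = np.zeros(n_ab)
    if scenario.prop_de > 0 and n_de < 1:
        warnings.warn("prop_de too small for any DE antibody; zero DE simulated")
    if n_de >= 1:
        de_idx = rng.choice(n_ab, size=n_de, replace=False)
        n_up = int(round(scenario.asym * n_de))
        up = de_idx[:n_up]
        down = de_idx[n_up:]
        truth_de[de_idx] = True
        truth_dir[up] = 1
        truth_dir[down] = -1
        truth_shift[de_idx] = sample_truncated_normal(
            scenario.shift_mean, scenario.shift_sd, n_de, rng
        )

    # per-spot shift vector
    ab_index = {ab: i for i, ab in enumerate(antibodies)}
    spot_ab = np.array([ab_index[g] for g in groups])
    spot_shift = (truth_shift * truth_dir)[spot_ab]

    arrays = []
    for j, arr in enumerate(baseline.arrays):
        new = arr.copy()
        if is_tumour[j] and n_de >= 1:
            l5 = np.log2(new.cy5)
            l3 = np.log2(new.cy3)
            m = (l5 - l3) + spot_shift
            a = 0.5 * (l5 + l3)
            new.cy5, new.cy3 = intensities_from_ma(m, a)
        new.provenance["group"] = labels[j]
        arrays.append(new)
    aset = ArraySet(arrays=arrays, group_label=labels)
    return SimulatedDataset(
        arrays=aset, truth_de=truth_de, truth_direction=truth_dir,
        truth_shift=truth_shift, scenario=scenario, run_seed=int(run_seed),
    )


def scenario_grid(n_runs: int = 100) -> list[Scenario]:
    """The default scenario grid: symmetric regulation at 20%/40% DE and
    fully asymmetric regulation at 10%-60% DE."""
    grid = [Scenario(prop_de=p, asym=0.5, n_runs=n_runs) for p in (0.2, 0.4)]
    grid += [
        Scenario(prop_de=p, asym=1.0, n_runs=n_runs)
        for p in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    ]
    return grid
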