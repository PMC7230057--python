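"""Sequential coordinate-wise optimization of the registration parameters.

The four nonrigid parameters (final grid spacing FGS, number of resolutions
NR, spatial samples per iteration NSS, iteration cap MNI) are swept one at a
time against the error measure: the mean distance between the observed
control points and the nonrigidly-transformed reference control points,
averaged over all acquisitions.  Each sweep fixes its optimum before the
next parameter is considered; the first parameter is optionally re-swept at
the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bspline import BSplineTransform
from .image import ImageVolume
from .register import RegistrationFailureError, RegistrationParams, bspline_register

__all__ = ["Acquisition", "SweepResult", "evaluate_params", "sequential_sweep", "DEFAULT_SEARCH_SPACE"]

# The search ranges are swept on these grids (every named landmark value of
# the ranges is included).
DEFAULT_SEARCH_SPACE = {
    "fgs": [5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0],
    "nr": [1, 2, 3, 4, 5, 6],
    "nss": [1000, 2000, 3000, 5000, 7000],
    "mni": [100, 200, 500, 1000],
}
DEFAULT_ORDER = ["fgs", "nr", "nss", "mni"]


@dataclass
class Acquisition:
    """One registration problem: pre-aligned volumes plus pre-paired CPs.

    ``reference_cps[i]`` and ``observed_cps[i]`` refer to the same grid
    vertex; the observed CPs are the template-matching measurements the
    registration is scored against.
    """

    reference: ImageVolume
    observed: ImageVolume
    reference_cps: np.ndarray  # (n, 3) mm
    observed_cps: np.ndarray  # (n, 3) mm
    name: str = ""


@dataclass
class SweepResult:
    parameter: str
    values: list
    mean_errors: list  # grand mean error (mm) per tested value
    std_errors: list  # std of per-acquisition means (mm)
    chosen: float | int
    context: dict = field(default_factory=dict)  # fixed params during the sweep


def _acquisition_seed(master_seed: int, index: int) -> int:
    """Deterministic per-acquisition seed below 2^31."""
    return int(np.random.default_rng([int(master_seed), int(index)]).integers(2**31))


def evaluate_params(
    acquisitions: list[Acquisition],
    params: RegistrationParams,
    return_transforms: bool = False,
):
    """Grand mean CP distance (mm) for one parameter setting.

    Runs the nonrigid registration on every acquisition, maps its reference
    CPs, and averages the distances to the observed CPs over all CPs of all
    acquisitions (CP-count-weighted).  Failed registrations are excluded
    with a warning.
    """
    if not acquisitions:
        raise ValueError("need at least one acquisition")
    all_dists = []
    per_acq = []
    transforms: list[BSplineTransform | None] = []
    for i, acq in enumerate(acquisitions):
        p = replace(params, seed=_acquisition_seed(params.seed, i))
        try:
            t = bspline_register(acq.reference, acq.observed, p)
        except RegistrationFailureError as exc:
            warnings.warn(f"registration failed on acquisition {acq.name or i}: {exc}")
            per_acq.append(np.nan)
            transforms.append(None)
            continue
        mapped = t.apply(acq.reference_cps)
        d = np.linalg.norm(mapped - acq.observed_cps, axis=1)
        all_dists.append(d)
        per_acq.append(float(d.mean()))
        transforms.append(t)
    if not all_dists:
        raise RegistrationFailureError("every acquisition failed")
    grand = float(np.concatenate(all_dists).mean())
    if return_transforms:
        return grand, per_acq, transforms
    return grand, per_acq


def sequential_sweep(
    acquisitions: list[Acquisition],
    search_space: dict | None = None,
    order: list[str] | None = None,
    initial: RegistrationParams | None = None,
    resweep_first: bool = True,
) -> list[SweepResult]:
    """Coordinate descent over the registration parameters.

    Sweeps the parameters in ``order``, fixing each sweep's optimum (the
    global minimum over the tested list; ties go to the smaller value)
    before the next sweep; optionally re-sweeps the first parameter with
    everything else fixed.  Deterministic given the seed in ``initial``.
    """
    search_space = dict(search_space or DEFAULT_SEARCH_SPACE)
    order = list(order or DEFAULT_ORDER)
    if len(set(order)) != len(order) or any(p not in search_space for p in order):
        raise ValueError("order must list distinct parameters present in the search space")
    for p, vals in search_space.items():
        if not vals:
            raise ValueError(f"empty value list for parameter {p!r}")
    # the initial context mirrors the published protocol: the first FGS
    # sweep runs at NR=4, NSS=3000, MNI=500
    params = initial if initial is not None else RegistrationParams(nr=4)

    results: list[SweepResult] = []

    def sweep_one(name: str, current: RegistrationParams) -> tuple[SweepResult, RegistrationParams]:
        values = list(search_space[name])
        means, stds = [], []
        for v in values:
            p = replace(current, **{name: v})
            grand, per_acq = evaluate_params(acquisitions, p)
            means.append(grand)
            stds.append(float(np.nanstd(per_acq)))
        best_i = min(range(len(values)), key=lambda i: (means[i], values[i]))
        chosen = values[best_i]
        res = SweepResult(
            parameter=name,
            values=values,
            mean_errors=means,
            std_errors=stds,
            chosen=chosen,
            context={k: getattr(current, k) for k in ("fgs", "nr", "nss", "mni") if k != name},
        )
        return res, replace(current, **{name: chosen})

    for name in order:
        res, params = sweep_one(name, params)
        results.append(res)
    if resweep_first and len(order) > 1:
        res, params = sweep_one(order[0], params)
        res.context["resweep"] = True
        results.append(res)
    return results
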