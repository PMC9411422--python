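"""Reference in-silico studies: the runs behind the reported numbers.

Thin, seedable wrappers that assemble the standard scenario
configurations (reference germ disc, reference germ band, the
perturbation panel) and reduce trajectories to the reported summary
quantities.  Replicate medians are taken over consecutive seeds derived
from a base seed.
"""

from __future__ import annotations

import numpy as np

from . import metrics, scenarios


def disc_run(seed, **over):
    """Reference germ disc scenario (64 -> 1,500 cells)."""
    cfg = scenarios.ScenarioConfig.germ_disc_defaults(seed=seed)
    for k, v in over.items():
        setattr(cfg, k, v)
    return scenarios.run_germ_disc(cfg)


def band_run(seed, gamma_scale=1.0, variant=None, scale=None, *,
             n_initial=None, target_count=None, extraembryonic_count=None,
             with_rd=False, **over):
    """Reference germ band scenario (1,500 -> 6,000 cells), optionally
    with the embryonic contraction rescaled or one perturbation variant
    applied; ``n_initial``/``target_count`` support reduced study
    sizes."""
    cfg = scenarios.ScenarioConfig.germ_band_defaults(seed=seed)
    if gamma_scale != 1.0:
        cfg = scenarios.apply_perturbation(cfg, "gamma_scale",
                                           gamma_scale)
    if variant is not None:
        cfg = scenarios.apply_perturbation(cfg, variant, scale)
    if n_initial is not None:
        cfg.n_initial = n_initial
    if extraembryonic_count is not None:
        cfg.extraembryonic_count = extraembryonic_count
    if target_count is not None:
        cfg.target_count = target_count
    cfg.with_rd = with_rd
    for k, v in over.items():
        setattr(cfg, k, v)
    return scenarios.run_germ_band(cfg)


def median_band_width(base_seed, gamma_scale=1.0, n_seeds=3, **kw):
    """Replicate-median midpoint width (um) of the germ-band end state
    over ``n_seeds`` consecutive seeds."""
    widths = []
    for k in range(n_seeds):
        traj = band_run(base_seed + k, gamma_scale=gamma_scale, **kw)
        widths.append(metrics.germ_band_width(traj.final_state, 0.5))
    return float(np.median(widths)), widths


def median_elongation(base_seed, n_seeds=2, variant=None, scale=None,
                      **kw):
    """Replicate-median elongation index of the germ-band end state."""
    vals = []
    for k in range(n_seeds):
        traj = band_run(base_seed + k, variant=variant, scale=scale, **kw)
        vals.append(metrics.elongation_index(traj.final_state))
    return float(np.median(vals)), vals
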