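"""Seeded recovery experiments on the synthetic phantoms.

These Monte-Carlo experiments score the pipeline against planted ground
truth: lesion-severity recovery (sensitivity/specificity of the -1.96
criterion on z = -3 lesions), standardized-beta recovery, logistic
confidence-interval coverage of a planted odds ratio, and the end-to-end
ranking of the severe-lesion indicator in the cohort logistic model.  They
are used by both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cstlesion import maps, phantom, pipeline, stats, tract

__all__ = [
    "severity_recovery",
    "planted_beta_recovery",
    "logistic_ci_coverage",
    "severe_indicator_ranking",
]


def _experiment_space() -> phantom.TemplateSpace:
    return phantom.build_phantom_space(
        shape=(24, 24, 110), tract_radius=2.0, fan_radius=3.5
    )


def planted_severity_specs(space: phantom.TemplateSpace) -> list[phantom.LesionSpec]:
    """Fixed, non-overlapping planted lesions: 3 severe (z=-3), 3 mild (z=-0.8).

    Each lesion spans at least 10 voxels (radius 2 mm in-plane, 4 mm
    along the axis on a 1 mm grid).
    """
    nx = space.shape[0]
    cx_left = nx // 2 - nx // 4
    cx_right = nx // 2 + nx // 4
    cy = space.shape[1] // 2
    radii = (2.0, 2.0, 4.0)
    zs = [20, 50, 70, 30, 60, 90]  # spaced along the I-S axis
    severities = [-3.0, -3.0, -3.0, -0.8, -0.8, -0.8]
    sides = ["left", "left", "left", "right", "right", "right"]
    specs = []
    for z, sz, side in zip(zs, severities, sides):
        cx = cx_left if side == "left" else cx_right
        specs.append(
            phantom.LesionSpec(centre=(cx, cy, z), radii=radii, severity_z=sz,
                               side=side)
        )
    return specs


def severity_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_hc: int = 21,
) -> dict:
    """Sensitivity/specificity of severity calls against planted truth.

    Per replicate: a fresh 21-subject HC atlas, one patient with 3 planted
    severe (z = -3) and 3 mild (z = -0.8) lesions of >= 10 voxels each;
    lesions are classified with the -1.96 criterion and scored against
    the planted severity.  Counts are pooled over replicates.
    """
    space = _experiment_space()
    specs = planted_severity_specs(space)
    rng = np.random.default_rng(base_seed)
    tp = fn = tn = fp = 0
    tract_mask = space.tract_mask("both")
    for _ in range(n_seeds):
        hc = phantom.simulate_hc_cohort(space, n=n_hc, seed=int(rng.integers(2**31)))
        atlas = maps.build_normative_atlas(
            [maps.QuantMap(s.quant_maps["MTR"]) for s in hc]
        )
        patient = phantom.simulate_patient(
            space, specs, seed=int(rng.integers(2**31))
        )
        zmap = maps.compute_zscore_map(
            maps.QuantMap(patient.quant_maps["MTR"]), atlas
        )
        components = tract.label_lesion_components(patient.lesion_mask, space)
        calls = tract.classify_lesion_severity(components, zmap, tract_mask)
        # match each component to its planted spec by centre membership
        for comp, call in zip(components, calls):
            idx = {tuple(v) for v in comp.voxel_indices}
            spec = next(s for s in specs if s.centre in idx)
            if spec.truth_severe:
                tp += call.severe
                fn += not call.severe
            else:
                fp += call.severe
                tn += not call.severe
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_severe_planted": tp + fn,
        "n_mild_planted": tn + fp,
        "n_seeds": n_seeds,
    }


def planted_beta_recovery(
    betas: tuple[float, ...] = (0.5, -0.3, 0.0),
    n: int = 200,
    n_seeds: int = 50,
    noise_sd: float = 1.0,
    base_seed: int = 0,
) -> np.ndarray:
    """Mean recovered standardized betas over seeded replicates.

    Predictors are independent standard normals, the outcome a linear
    combination with the planted coefficients plus Gaussian noise; each
    replicate is fitted with :func:`cstlesion.stats.fit_multivariable_linear`
    and the recovered standardized betas (rescaled to the generating scale
    via the outcome SD) are averaged.
    """
    rng = np.random.default_rng(base_seed)
    k = len(betas)
    est = np.zeros((n_seeds, k))
    for s in range(n_seeds):
        X = rng.standard_normal((n, k))
        y = X @ np.asarray(betas) + noise_sd * rng.standard_normal(n)
        res = stats.fit_multivariable_linear(
            y, pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
        )
        # standardized betas are on the unit-outcome scale; undo it
        est[s] = res.beta.to_numpy() * y.std(ddof=1)
    return est.mean(axis=0)


def logistic_ci_coverage(
    log_or: float = float(np.log(1.74)),
    n: int = 2000,
    n_seeds: int = 100,
    base_seed: int = 0,
) -> dict:
    """Coverage of the Wald 95% CI for a planted log-odds-ratio.

    A binary exposure (p = 0.5) shifts the logit of a binary outcome by
    ``log_or`` from a baseline of -1; per replicate the logistic model is
    fitted and the replicate counts as covered if the 95% CI contains the
    planted odds ratio.
    """
    rng = np.random.default_rng(base_seed)
    covered = 0
    for _ in range(n_seeds):
        x = (rng.random(n) < 0.5).astype(float)
        logit = -1.0 + log_or * x
        p = 1.0 / (1.0 + np.exp(-logit))
        y = (rng.random(n) < p).astype(float)
        res = stats.fit_logistic(y, pd.DataFrame({"exposure": x}))
        if res.ci_low["exposure"] <= np.exp(log_or) <= res.ci_high["exposure"]:
            covered += 1
    return {"coverage": covered / n_seeds, "n_seeds": n_seeds, "n": n}


def severe_indicator_ranking(
    n_seeds: int = 100,
    base_seed: int = 0,
    config: pipeline.PipelineConfig | None = None,
) -> dict:
    """End-to-end check that the severe-lesion indicator dominates.

    Runs the full pipeline (21 HC, 35 patients / 70 functional sides) for
    each seed and counts the seeds in which the spinal-cord severe-lesion
    indicator carries the largest |Wald z| in the lower-limb CMCT logistic
    model.  Seeds where the logistic model fails (e.g. separation at this
    cohort size) count as failures.
    """
    base_config = config if config is not None else pipeline.PipelineConfig()
    top = 0
    failed = 0
    for s in range(n_seeds):
        cfg = pipeline.PipelineConfig(
            **{**base_config.to_dict(), "seed": base_seed + s,
               "shape": tuple(base_config.shape),
               "voxel_size": tuple(base_config.voxel_size),
               "site_effects": {k: tuple(v) for k, v in base_config.site_effects.items()}}
        )
        bundle = pipeline.run_pipeline(cfg)
        res = getattr(bundle, "logit_result", None)
        if res is None:
            failed += 1
            continue
        if res.top_predictor() == "severe_sc":
            top += 1
    return {"fraction_top": top / n_seeds, "n_seeds": n_seeds, "failed_fits": failed}
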