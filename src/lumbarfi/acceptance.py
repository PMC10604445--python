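"""Replicated validation experiments used by the acceptance checks.

Each function regenerates its inputs from a seed and measures the quantity
of interest by running the package end to end: cohort replicates for the
rank-correlation and regression-recovery summaries, phantom batteries for
the measurement-error summaries.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as sps

from .cohort import calibrate_defaults, generate_cohort
from .composition import MeasureConfig, measure_muscle
from .phantom import EllipseRegion, PhantomSpec, generate_phantom
from .stats import fit_regression

N_FEMALE = 110
N_MALE = 80
N_TOTAL = 190


def replicate_seeds(seed: int, n_rep: int) -> np.ndarray:
    """n_rep independent sub-seeds (< 2^31) derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n_rep) % (2**31)


def mean_fi_spearman(sex: str, seed: int, n_rep: int = 200) -> dict:
    """Mean Spearman rho(FI_PPM, FI_Psoas) over single-sex cohort replicates."""
    spec = calibrate_defaults()
    if sex == "female":
        spec = replace(spec, n=N_FEMALE, p_female=1.0)
    elif sex == "male":
        spec = replace(spec, n=N_MALE, p_female=0.0)
    else:
        raise ValueError(sex)
    rhos = []
    for s in replicate_seeds(seed, n_rep):
        df = generate_cohort(spec, seed=int(s)).df
        rhos.append(sps.spearmanr(df.FI_PPM, df.FI_Psoas).statistic)
    return {"mean_rho": float(np.mean(rhos)), "n": spec.n, "n_rep": n_rep}


def regression_recovery(seed: int, n_rep: int = 200) -> dict:
    """Mean refit of the generating FI_Psoas model over full-cohort replicates."""
    spec = calibrate_defaults()
    bs, betas, adj = [], [], []
    for s in replicate_seeds(seed, n_rep):
        df = generate_cohort(spec, seed=int(s)).df
        rep = fit_regression(df)
        bs.append(rep.table.loc["FI_PPM", "b"])
        betas.append(rep.table.loc["FI_PPM", "beta"])
        adj.append(rep.adj_r_squared)
    return {
        "mean_b_fi_ppm": float(np.mean(bs)),
        "mean_beta_fi_ppm": float(np.mean(betas)),
        "mean_adj_r_squared": float(np.mean(adj)),
        "n": spec.n,
        "n_rep": n_rep,
    }


def validation_spec(fraction: float, seed: int, **overrides) -> PhantomSpec:
    base = dict(
        image_height_px=96,
        image_width_px=96,
        regions=(EllipseRegion("PPM", "left", (48, 48), (38, 38)),),
        true_fat_fraction={("PPM", "left"): float(fraction)},
        mu_muscle=100.0,
        mu_fat=130.0,
        noise_sd=0.0,
        seed=seed,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def fi_recovery_errors(seed: int, fractions=None) -> dict:
    """|measured - true| FI on clean phantoms, in units of one pixel of area."""
    if fractions is None:
        fractions = np.arange(0.05, 0.61, 0.05)
    worst = 0.0
    n_px = 0
    for frac in fractions:
        ph = generate_phantom(validation_spec(frac, seed))
        comp = measure_muscle(ph.image, ph.masks, 1)
        truth = 100.0 * ph.truth_fat_fraction[("PPM", "left")]
        n_px = comp.n_pixels
        worst = max(worst, abs(comp.FI - truth) * n_px / 100.0)  # pixels of area
    return {"max_error_pixels": float(worst), "n": n_px}


# linear shading: 1.5x max/min across the validation region
BENEFIT_BIAS = (1.0, 0.25, 0.0, 0.0, 0.0, 0.0)


def bias_correction_benefit(seed: int, n_rep: int = 20, noise_sd: float = 0.6) -> dict:
    """Mean |FI error| with vs without correction under strong shading."""
    err_on, err_off = [], []
    for s in replicate_seeds(seed, n_rep):
        ph = generate_phantom(
            validation_spec(0.40, int(s), bias_coefficients=BENEFIT_BIAS, noise_sd=noise_sd)
        )
        truth = 100.0 * ph.truth_fat_fraction[("PPM", "left")]
        on = measure_muscle(ph.image, ph.masks, 1)
        off = measure_muscle(ph.image, ph.masks, 1, MeasureConfig(bias_correction=False))
        err_on.append(abs(on.FI - truth))
        err_off.append(abs(off.FI - truth))
    return {
        "mean_error_corrected": float(np.mean(err_on)),
        "mean_error_uncorrected": float(np.mean(err_off)),
        "n_rep": n_rep,
    }
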