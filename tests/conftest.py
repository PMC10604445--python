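import numpy as np
import pytest

from lumbarfi.phantom import EllipseRegion, PhantomSpec, default_spec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free phantom with the default L4-like layout."""
    return generate_phantom(default_spec(seed=11))


def single_region_spec(**overrides) -> PhantomSpec:
    """One large elliptical region: the bias field varies strongly across it."""
    base = dict(
        image_height_px=96,
        image_width_px=96,
        regions=(EllipseRegion("PPM", "left", (48, 48), (38, 38)),),
        true_fat_fraction={("PPM", "left"): 0.40},
        mu_muscle=100.0,
        mu_fat=130.0,
        noise_sd=0.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def brute_force_otsu(values: np.ndarray) -> float:
    """Independent oracle: exhaustive between-class variance maximization.

    Tries every cut between consecutive distinct sorted values and returns
    the midpoint of the best cut.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best, best_cut = -np.inf, None
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        lo, hi = v[:i], v[i:]
        w0, w1 = lo.size / n, hi.size / n
        sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sb > best:
            best, best_cut = sb, 0.5 * (v[i - 1] + v[i])
    return best_cut


def brute_force_mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: U as the explicit count of pairwise wins (+ half ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def rank_formula_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = np.sum((rx - ry) ** 2)
    n = x.size
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
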