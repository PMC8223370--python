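"""Spearman rho, percentile bootstrap, and windowed pooling."""

import numpy as np
import pytest
from scipy import stats

from cytodyna import (
    InsufficientDataError,
    UndefinedCorrelationError,
    bootstrap_ci,
    spearman_rho,
    window_correlation,
)
from cytodyna.correlate import window_times

from conftest import cohort_from_blocks


# --- spearman_rho -----------------------------------------------------------

def test_monotone_transform_gives_one():
    x = np.array([0.3, 1.2, 5.0, 7.7, 9.1])
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho(x, x ** 3) == pytest.approx(1.0)


def test_reversed_gives_minus_one():
    assert spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)


def test_midrank_hand_oracle():
    """x=(1,2,2,4), y=(3,1,4,4): midranks x=(1,2.5,2.5,4), y=(2,1,3.5,3.5);
    Pearson of those ranks is 2.25/4.5 = 0.5 (hand-computed)."""
    x, y = [1, 2, 2, 4], [3, 1, 4, 4]
    # independent brute-force midrank computation
    def midrank(v):
        v = np.asarray(v, float)
        return np.array([
            np.mean(np.flatnonzero(np.sort(v) == vi)) + 1 for vi in v
        ])
    rx, ry = midrank(x), midrank(y)
    brute = np.corrcoef(rx, ry)[0, 1]
    assert brute == pytest.approx(0.5)
    assert spearman_rho(x, y) == pytest.approx(0.5)


def test_no_ties_closed_form():
    """Without ties rho equals 1 - 6*sum(d^2)/(n(n^2-1))."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(4, 30))
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        d = stats.rankdata(x) - stats.rankdata(y)
        closed = 1 - 6 * (d ** 2).sum() / (n * (n ** 2 - 1))
        assert spearman_rho(x, y) == pytest.approx(closed, abs=1e-12)


def test_constant_vector_undefined():
    with pytest.raises(UndefinedCorrelationError):
        spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


# --- bootstrap_ci -----------------------------------------------------------

def test_perfect_association_degenerate_ci():
    x = np.arange(10.0)
    lo, hi = bootstrap_ci(x, x, B=200, seed=0)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert bootstrap_ci(x, y, seed=11) == bootstrap_ci(x, y, seed=11)
    assert bootstrap_ci(x, y, seed=11) != bootstrap_ci(x, y, seed=12)


def test_bootstrap_needs_four_points():
    with pytest.raises(InsufficientDataError):
        bootstrap_ci([1, 2, 3], [1, 2, 3])


def test_ci_width_shrinks_with_n():
    rng = np.random.default_rng(2)
    cov = [[1, 0.5], [0.5, 1]]
    widths = {}
    for n in (10, 40):
        ws = []
        for _ in range(40):
            z = rng.multivariate_normal([0, 0], cov, size=n)
            lo, hi = bootstrap_ci(z[:, 0], z[:, 1], B=400, seed=rng)
            ws.append(hi - lo)
        widths[n] = np.median(ws)
    assert widths[40] < widths[10]


# --- windowed correlation ---------------------------------------------------

def test_window_membership_boundary():
    times = [0.0, 1.0, 4.0, 6.0, 12.0, 24.0, 48.0]
    assert window_times((0, 12), times) == [0.0, 1.0, 4.0, 6.0, 12.0]
    assert window_times((12, 48), times) == [12.0, 24.0, 48.0]
    # 12 h belongs to both canonical windows by default
    assert window_times((0, 12), times, "exclusive-upper") == [0.0, 1.0, 4.0, 6.0]
    assert window_times((12, 48), times, "exclusive-upper") == [12.0, 24.0, 48.0]


def _window_cohort(small_panel, rng, rho_late=0.9):
    blocks = []
    for t in (0.0, 1.0, 4.0, 6.0, 12.0):
        blocks.append(("WT", "heart", t, np.exp(rng.normal(0, 0.3, (6, 6)))))
    for t in (24.0, 48.0):
        z = rng.multivariate_normal(
            [0, 0], [[1, rho_late], [rho_late, 1]], size=6
        )
        vals = np.exp(rng.normal(1.5, 0.3, (6, 6)))
        vals[:, 0] = np.exp(0.3 * z[:, 0] + 1.5)
        vals[:, 1] = np.exp(0.3 * z[:, 1] + 1.5)
        blocks.append(("WT", "heart", t, vals))
    return cohort_from_blocks(blocks, small_panel)


def test_window_correlation_pools_window_animals(small_panel):
    rng = np.random.default_rng(3)
    cohort = _window_cohort(small_panel, rng)
    ci = window_correlation(
        cohort, "WT", "heart", ("TNF", "IL-6"), (12, 48), B=200, seed=0
    )
    assert ci.n == 18  # 12, 24, 48 h x 6 animals
    assert ci.ci_low <= ci.rho <= ci.ci_high or ci.rho_outside_ci


def test_self_pair_flagged(small_panel):
    rng = np.random.default_rng(4)
    cohort = _window_cohort(small_panel, rng)
    with pytest.warns(UserWarning, match="self-pair"):
        ci = window_correlation(
            cohort, "WT", "heart", ("TNF", "TNF"), (0, 12), B=100, seed=0
        )
    assert ci.rho == 1.0


def test_window_insufficient_data(small_panel):
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, np.full((3, 6), 2.0))], small_panel
    )
    with pytest.raises(InsufficientDataError):
        window_correlation(
            cohort, "WT", "heart", ("TNF", "IL-6"), (0, 12), B=100, seed=0
        )
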