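"""Shared fixtures: rendered calibration series and the noisy benchmark.

The expensive rendered populations are session-scoped so the unit tests and
the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mcascreen import imaging, synthetic


def render_spheroid_series(n=50, d_lo=150.0, d_hi=550.0, h0=140.0):
    """Noiseless spherical aggregates with diameters evenly spanning a range."""
    optics = synthetic.OpticsConfig(h0=h0)
    feats = []
    for D in np.linspace(d_lo, d_hi, n):
        g = synthetic.MCAGeometry("spheroid", a=D / 2, b=D / 2)
        feats.append(imaging.analyze_frame(synthetic.render_frame(g, optics), h0=h0))
    return feats


def render_cyst_series(n=50, d_lo=150.0, d_hi=550.0, ratio=3.24, h0=140.0):
    """Noiseless spherical cysts with the proportional monolayer rule t = D/ratio."""
    optics = synthetic.OpticsConfig(h0=h0)
    feats = []
    for D in np.linspace(d_lo, d_hi, n):
        g = synthetic.MCAGeometry("cyst", a=D / 2, b=D / 2, t=D / ratio)
        feats.append(imaging.analyze_frame(synthetic.render_frame(g, optics), h0=h0))
    return feats


def run_classifier_benchmark(n_per_class=500, noise_sd=0.02, seed=42):
    """Noisy rendered cyst/spheroid benchmark; returns a ClassificationReport."""
    rng = np.random.default_rng(seed)
    optics = synthetic.OpticsConfig(noise_sd=noise_sd)
    cysts = synthetic.sample_population(
        synthetic.PopulationConfig(n=n_per_class, cyst_fraction=1.0, seed=seed + 1)
    )
    spheroids = synthetic.sample_population(
        synthetic.PopulationConfig(n=n_per_class, cyst_fraction=0.0, seed=seed + 2)
    )
    predicted, truth = [], []
    for g in cysts + spheroids:
        fv = imaging.analyze_frame(synthetic.render_frame(g, optics, rng=rng))
        if fv is None:
            continue
        predicted.append(imaging.classify_phenotype(fv))
        truth.append(g.kind)
    return imaging.evaluate_classifier(predicted, truth)


@pytest.fixture(scope="session")
def spheroid_series_features():
    return render_spheroid_series()


@pytest.fixture(scope="session")
def cyst_series_features():
    return render_cyst_series()


@pytest.fixture(scope="session")
def classifier_benchmark_report():
    return run_classifier_benchmark()
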