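"""Shared fixtures: default calibrations and small synthetic sessions."""

import numpy as np
import pytest

import pulsedecomp as pdc


@pytest.fixture(scope="session")
def tree():
    return pdc.default_tree()


@pytest.fixture(scope="session")
def coeffs():
    return pdc.default_coefficients()


@pytest.fixture(scope="session")
def model_link(tree, coeffs):
    return (tree, coeffs)


@pytest.fixture(scope="session")
def clean_session(model_link):
    """One 60-beat noise-free single-stage session (default morphology)."""
    spec = pdc.SessionSpec(
        stages=(pdc.StageSpec(lbnp_mmhg=0, duration_s=60.0),),
        noise_sd=0.0,
        seed=11,
    )
    stream, truth = pdc.synthesize_session(spec, model_link=model_link)
    return spec, stream, truth


@pytest.fixture(scope="session")
def noisy_session(model_link):
    """Five-stage model-linked session at default (2%) noise."""
    spec = pdc.default_session_spec(seed=1, stage_duration_s=40.0)
    stream, truth = pdc.synthesize_session(spec, model_link=model_link)
    return spec, stream, truth


@pytest.fixture(scope="session")
def noisy_extraction(noisy_session):
    spec, stream, truth = noisy_session
    beats, report = pdc.extract_session(
        pdc.DerivativeStream(stream, spec.sample_rate), truth=truth
    )
    return spec, truth, beats, report


def match_beats_to_truth(beats, truth, tol_samples=60):
    """Associate extracted beats with truth rows by onset proximity."""
    import pandas as pd

    bb = beats.sort_values("onset_sample").copy()
    bb["onset_sample"] = bb["onset_sample"].astype("int64")
    tt = truth.sort_values("onset_sample").copy()
    tt["onset_sample"] = tt["onset_sample"].astype("int64")
    merged = pd.merge_asof(
        bb, tt, on="onset_sample", direction="nearest",
        tolerance=tol_samples, suffixes=("", "_true"),
    )
    return merged.dropna(subset=["t13_ms"])
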