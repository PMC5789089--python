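"""Shared fixtures: optical configuration, stage templates and synthetic
movies are expensive to build, so they are session-scoped and reused."""

import numpy as np
import pytest

from polcurve import (
    MovieConfig,
    OpticalConfig,
    StageTemplates,
    bias_calibrate,
    dark_frames,
    render_movie,
    sample_events,
)


@pytest.fixture(scope="session")
def optical() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def templates(optical) -> StageTemplates:
    return StageTemplates(optical)


@pytest.fixture(scope="session")
def small_movie(optical, templates):
    """A 60-event noisy movie with ground truth and dark frames, shared by
    the tracking/classification tests."""
    mc = MovieConfig(field_px=128, n_frames=300, seed=7)
    events = sample_events(
        60, field_size=mc.field_px * optical.pixel, duration=mc.duration, seed=8
    )
    stack, truth = render_movie(events, optical, mc, templates=templates)
    bias = bias_calibrate(dark_frames(mc))
    return {"stack": stack, "truth": truth, "bias": bias, "movie_config": mc, "events": events}


@pytest.fixture(scope="session")
def acceptance_movie(optical, templates):
    """The large (220-event) movie used by the population-statistics
    acceptance checks."""
    mc = MovieConfig(field_px=192, n_frames=320, seed=11)
    events = sample_events(
        220, field_size=mc.field_px * optical.pixel, duration=mc.duration, seed=12
    )
    stack, truth = render_movie(events, optical, mc, templates=templates)
    bias = bias_calibrate(dark_frames(mc))
    return {"stack": stack, "truth": truth, "bias": bias, "movie_config": mc, "events": events}


@pytest.fixture(scope="session")
def analyzed_acceptance(acceptance_movie):
    from polcurve import analyze_movie, match_to_truth

    table, tracks, summary = analyze_movie(
        acceptance_movie["stack"], bias=acceptance_movie["bias"]
    )
    matched = match_to_truth(table, acceptance_movie["truth"])
    return {"table": table, "tracks": tracks, "summary": summary, "matched": matched}
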