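import numpy as np
import pytest

from breathflow import msio, synth

# A compressed three-ramp program for unit-scale fixtures: same structure
# as the real acquisition, desk-scale length.
SHORT_PROGRAM = msio.TemperatureProgram(((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)))


def clean_design(**overrides) -> synth.CohortDesign:
    """Noise-free, drift-free design on the short program."""
    kw = dict(
        noise_sd=0.0,
        baseline_level=0.0,
        rt_jitter_sd=0.0,
        sample_shift_sd=0.0,
        program=SHORT_PROGRAM,
        mz_range=(38, 150),
        artifact_compounds=[],
        alkane_carbons=(),
        include_alkane_ladder=False,
        include_voc_standard=False,
    )
    kw.update(overrides)
    return synth.CohortDesign(**kw)


def gaussian_compound(name, spectrum, rt, sigma=0.02) -> synth.TrueCompound:
    return synth.TrueCompound(name, spectrum, rt_mean=rt, peak_sigma=sigma)


@pytest.fixture
def single_peak_run():
    """One noiseless single-ion compound at 1.5 min, apex height 1e5."""
    comp = gaussian_compound("tol", {91: 1000.0}, 1.5)
    comp.abundance_by_sample["s1"] = 1e5
    run = synth.simulate_run(
        [comp], clean_design(), "s1", "group1", "mother", jitter_sd=0
    )
    return run, comp


@pytest.fixture(scope="session")
def demo_run():
    """The full workflow on the seeded demonstration cohort (shared)."""
    from breathflow.pipeline import PipelineConfig, demo_cohort, run_pipeline

    import tempfile

    cohort, library = demo_cohort(1)
    with tempfile.TemporaryDirectory() as tmp:
        cfg = PipelineConfig(outdir=tmp, seed=1)
        result = run_pipeline(cfg, runs=cohort.runs, library=library)
        yield cohort, result
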