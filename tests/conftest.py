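import pytest

from morphopool import NoiseModel, simulate_study, sigma_from_mean_error
from morphopool.synthetic import ScanSlot, StudyDesign


def cs1mm_design(n_subjects: int, n_scans: int = 8) -> StudyDesign:
    """Stripped-down design: one group, only CS 1.0 mm scans per session."""
    plan = tuple(
        ScanSlot("CS", 1.0, "pre" if i <= n_scans // 2 else "post", i, i)
        for i in range(1, n_scans + 1)
    )
    return StudyDesign(groups=(("YA-CU", n_subjects),), sessions=2, scan_plan=plan)


@pytest.fixture(scope="session")
def small_table():
    """Full protocol, 6 subjects (2 per group), default tuned noise model."""
    from morphopool import default_noise_model
    from morphopool.synthetic import default_design

    base = default_design()
    design = StudyDesign(
        groups=(("YA-CU", 2), ("OA-CU", 2), ("MCI/AD", 2)),
        sessions=2,
        scan_plan=base.scan_plan,
    )
    return simulate_study(default_noise_model(seed=7), design, seed=7)


@pytest.fixture(scope="session")
def noiseless_table():
    """Degenerate model: every scan returns the subject's exact true value."""
    from morphopool.synthetic import default_design

    base = default_design()
    design = StudyDesign(
        groups=(("YA-CU", 2), ("MCI/AD", 1)), sessions=2, scan_plan=base.scan_plan
    )
    model = NoiseModel(subject_cv=0.1)
    return simulate_study(model, design, seed=3)


@pytest.fixture(scope="session")
def uncorrelated_table():
    """40 subjects, 8 CS 1.0 mm scans/session, independent errors (~3% e1)."""
    model = NoiseModel(sigma_scan=sigma_from_mean_error(3.0))
    return simulate_study(model, cs1mm_design(40), seed=17)
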