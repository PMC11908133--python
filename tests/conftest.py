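import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonedyn.growth import GrowthModelParams
from clonedyn.io import MutationObservation, Trajectory

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def params():
    return GrowthModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_obs(pid, gene, variant, age, alt, depth, uao=None, gnomad=None, cohort="synthetic"):
    return MutationObservation(
        participant_id=pid,
        cohort=cohort,
        gene=gene,
        variant=variant,
        age=float(age),
        alt_reads=int(alt),
        depth=int(depth),
        vaf=alt / depth,
        unique_alt_reads=uao,
        gnomad_p=gnomad,
    )


def make_trajectory(pid, gene, variant, ages, alts, depths):
    obs = [
        make_obs(pid, gene, variant, a, k, d)
        for a, k, d in zip(ages, alts, depths)
    ]
    return Trajectory(pid, gene, variant, obs)


@pytest.fixture
def five_variant_fixture():
    """Toy filter table: 5 variants over 3 waves, exactly 2 pass all rules.

    v1 passes at later waves (first wave below the VAF threshold, still
    kept via the all-matched-points rule); v2 fails read support (AO);
    v3 is germline-stable around VAF 0.5; v4 never reaches the VAF
    threshold; v5 passes everywhere.
    """
    rows = []
    waves = (70.0, 76.0, 82.0)
    # v1: growing clone, below threshold at wave 1
    for age, alt in zip(waves, (10, 60, 180)):
        rows.append(make_obs("P1", "DNMT3A", "v1", age, alt, 2000, uao=alt // 2, gnomad=0.001))
    # v2: VAF fine (depth 200 -> vaf 0.015..0.02) but AO always 4
    for age, alt, d in zip(waves, (4, 4, 4), (260, 240, 200)):
        rows.append(make_obs("P1", "TET2", "v2", age, alt, d, uao=3, gnomad=0.001))
    # v3: germline-stable near 0.5
    for age, alt in zip(waves, (1000, 980, 1020)):
        rows.append(make_obs("P1", "JAK2", "v3", age, alt, 2000, uao=500, gnomad=0.001))
    # v4: VAF stuck at 0.5%
    for age, alt in zip(waves, (10, 11, 9)):
        rows.append(make_obs("P1", "ASXL1", "v4", age, alt, 2000, uao=6, gnomad=0.001))
    # v5: clean passing variant
    for age, alt in zip(waves, (50, 90, 160)):
        rows.append(make_obs("P1", "SF3B1", "v5", age, alt, 2000, uao=30, gnomad=0.01))
    expected_kept = {"DNMT3A:v1", "SF3B1:v5"}
    expected_reasons = {"TET2:v2": "AO", "JAK2:v3": "germline-stable", "ASXL1:v4": "VAF"}
    return rows, expected_kept, expected_reasons
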