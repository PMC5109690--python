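import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from snvforest.features import FEATURE_NAMES
from snvforest.forest import TrainingInstance
from snvforest.pileup_io import PileupRecord, ReadObservation, SitePair


def make_record(chrom="chr1", pos=100, ref="A", obs=None, depth=None):
    obs = obs or []
    return PileupRecord(chrom, pos, ref, depth if depth is not None else len(obs), list(obs))


def make_obs(allele="A", strand="+", bqv=35, mqv=50, read_pos=40, **kw):
    return ReadObservation(allele, strand, bqv, mqv, read_pos, **kw)


def uniform_site(ref="A", alt="C", n_ref=20, n_alt=5, n_ref_normal=25,
                 n_alt_normal=0, pos=100, alt_bqv=35, alt_mqv=50):
    """A matched site with clean reference reads and configurable alt."""
    rng = np.random.default_rng(pos)
    def reads(n, allele, bqv, mqv):
        return [make_obs(allele, "+" if rng.random() < 0.5 else "-", bqv, mqv,
                         int(rng.integers(1, 101))) for _ in range(n)]
    tumor = make_record(pos=pos, ref=ref,
                        obs=reads(n_ref, ref, 36, 55) + reads(n_alt, alt, alt_bqv, alt_mqv))
    normal = make_record(pos=pos, ref=ref,
                         obs=reads(n_ref_normal, ref, 36, 55) + reads(n_alt_normal, alt, alt_bqv, alt_mqv))
    return SitePair(tumor, normal)


@pytest.fixture
def neutral_background():
    from snvforest.features import BackgroundMedians
    return BackgroundMedians(
        {"mean_bqv": 36.0, "mean_mqv": 55.0, "tumor_depth": 30.0,
         "normal_depth": 30.0}, n_positions=1000, seed=0)


def feature_instances(n_tp, n_fp, seed=0, shift=2.0, n_informative=5):
    """Feature-level synthetic training set: TP instances shifted from FP in
    the first ``n_informative`` features."""
    rng = np.random.default_rng(seed)
    delta = np.zeros(len(FEATURE_NAMES))
    delta[:n_informative] = shift
    out = []
    for _ in range(n_tp):
        out.append(TrainingInstance(
            dict(zip(FEATURE_NAMES, rng.normal(0, 1, len(FEATURE_NAMES)) + delta)), "TP"))
    for _ in range(n_fp):
        out.append(TrainingInstance(
            dict(zip(FEATURE_NAMES, rng.normal(0, 1, len(FEATURE_NAMES)))), "FP"))
    return out


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A modest simulated matched pair shared across pipeline tests."""
    from snvforest.simulate import SimulationConfig, simulate_pair

    d = tmp_path_factory.mktemp("small_cohort")
    cfg = SimulationConfig(n_sites=4000, n_somatic=30, n_germline=20,
                           error_rate=0.02, seed=42)
    tumor, normal, truth = simulate_pair(cfg, d)
    return {"dir": d, "tumor": tumor, "normal": normal, "truth": truth, "cfg": cfg}
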