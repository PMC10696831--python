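"""Shared fixtures: hand-built micro-arrays and small simulated studies.

All fixtures are generated programmatically; session scope keeps the
simulated studies to one build per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methnorm.core import IntensityData, ProbeAnnotation, SampleSheet
from methnorm.simulate import BatchParams, SimulationConfig, simulate_study


def make_annotation(n_plain=6, n_dmr=2, n_snp=2, n_x=2, seed=0,
                    type2_fraction=0.5) -> ProbeAnnotation:
    rng = np.random.default_rng(seed)
    classes = (["plain"] * n_plain + ["dmr"] * n_dmr + ["snp"] * n_snp +
               ["chrX_sex"] * n_x)
    n = len(classes)
    ids = [f"cg{i:05d}" for i in range(n)]
    is_t2 = rng.random(n) < type2_fraction
    table = pd.DataFrame({
        "design_type": np.where(is_t2, "II", "I"),
        "channel": np.where(is_t2, "Both",
                            np.where(rng.random(n) < 0.5, "Grn", "Red")),
        "chromosome": np.where(np.array(classes) == "chrX_sex", "X", "1"),
        "special_class": classes,
        "cpg_count": rng.choice([1, 2, 3], size=n),
    }, index=pd.Index(ids, name="probe_id"))
    return ProbeAnnotation(table)


def make_samples(n=4, cohort="C", prefix="S", seed=0) -> SampleSheet:
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    table = pd.DataFrame({
        "cohort": cohort, "batch": "b1",
        "age": rng.normal(79, 0.6, n),
        "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
        "bmi": rng.uniform(20, 35, n),
    }, index=pd.Index(ids, name="sample_id"))
    for k in range(3):
        table[f"pc{k + 1}"] = rng.normal(0, 1, n)
    return SampleSheet(table)


def make_intensities(annotation=None, samples=None, seed=0,
                     with_oob=True) -> IntensityData:
    annotation = annotation or make_annotation()
    samples = samples or make_samples()
    rng = np.random.default_rng(seed)
    shape = (len(annotation), len(samples))
    idx, cols = annotation.probe_ids, samples.sample_ids

    def df(a):
        return pd.DataFrame(a, index=idx, columns=cols)

    kw = {}
    if with_oob:
        oob = np.abs(rng.normal(300, 30, shape))
        oob = np.where(annotation.is_type("I")[:, None], oob, np.nan)
        kw = {"oob_meth": df(oob), "oob_unmeth": df(oob * 1.02)}
    return IntensityData(
        meth=df(rng.uniform(100, 8000, shape)),
        unmeth=df(rng.uniform(100, 8000, shape)),
        annotation=annotation, samples=samples,
        beadcount=df(rng.integers(5, 25, shape)),
        detection_p=df(rng.uniform(0, 1e-4, shape)), **kw)


SMALL_CONFIG = dict(n_plain=900, n_dmr=40, n_snp=40, n_x=60, n_samples=40)


@pytest.fixture(scope="session")
def small_study():
    """Two cohorts, 1,040 probes x 40 samples each, default batches
    (different backgrounds and dye gains)."""
    return simulate_study(SimulationConfig(**SMALL_CONFIG, seed=11))


@pytest.fixture(scope="session")
def matched_batch_study():
    """Same biology, both cohorts rendered under identical batch
    conditions (technical null)."""
    bp = BatchParams()
    return simulate_study(SimulationConfig(**SMALL_CONFIG, batch_a=bp,
                                           batch_b=bp, seed=13))


@pytest.fixture()
def tiny_data():
    return make_intensities()
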