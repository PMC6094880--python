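import math

import numpy as np
import pytest

from jdmjm import (
    OUTCOME_NAMES,
    default_outcome_specs,
    inverse_transform,
    remission_indicator,
    transform_outcome,
)


def test_outcome_names_order():
    assert OUTCOME_NAMES == ("ck", "cmas", "mmt8", "pga")


def test_transforms_match_definitions():
    specs = default_outcome_specs()
    assert transform_outcome(specs["ck"], math.e) == pytest.approx(1.0)
    assert transform_outcome(specs["cmas"], 49.0) == pytest.approx(7.0)
    assert transform_outcome(specs["pga"], 4.0) == pytest.approx(2.0)


def test_round_trip_inverse_transform():
    specs = default_outcome_specs()
    rng = np.random.default_rng(0)
    for name in OUTCOME_NAMES:
        spec = specs[name]
        lo = max(spec.lower_bound, 1e-3) if name == "ck" else spec.lower_bound
        vals = rng.uniform(lo, min(spec.upper_bound, 1e4), size=200)
        back = np.array([inverse_transform(spec, transform_outcome(spec, v))
                         for v in vals])
        assert np.max(np.abs(back - vals) / np.maximum(vals, 1.0)) < 1e-10


def test_continuous_support_excludes_best_value():
    specs = default_outcome_specs()
    lo, hi = specs["cmas"].continuous_support()
    assert hi == pytest.approx(math.sqrt(52.0))
    lo, hi = specs["pga"].continuous_support()
    assert lo == pytest.approx(0.0)
    assert hi == pytest.approx(math.sqrt(10.0))
    # CK has no hurdle: support is the whole transformed range
    lo, hi = specs["ck"].continuous_support()
    assert lo == -np.inf and hi == np.inf


def test_is_best_and_inactive():
    specs = default_outcome_specs()
    assert specs["cmas"].is_best(52.0)
    assert not specs["cmas"].is_best(51.0)
    assert specs["cmas"].is_inactive(48.0)
    assert not specs["cmas"].is_inactive(47.9)
    assert specs["ck"].is_inactive(150.0)
    assert not specs["ck"].is_inactive(150.1)
    assert specs["pga"].is_inactive(0.2)
    assert not specs["pga"].is_inactive(0.3)


def test_remission_indicator_labels():
    specs = default_outcome_specs()
    assert remission_indicator(specs["ck"], 80.0) == "inactive"
    assert remission_indicator(specs["ck"], 800.0) == "active"
    assert remission_indicator(specs["pga"], 0.0) == "inactive"
    assert remission_indicator(specs["mmt8"], 60.0) == "active"


def test_best_value_must_sit_on_boundary():
    from jdmjm import OutcomeSpec

    with pytest.raises(ValueError):
        OutcomeSpec(name="cmas", unit="points", lower_bound=0.0,
                    upper_bound=52.0, best_value=50.0, transform="sqrt",
                    remission_cutoff=48.0, cutoff_direction="ge")
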