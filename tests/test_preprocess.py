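import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squigclass.preprocess import (
    DegenerateSignalError,
    EmptyDatasetError,
    PreprocessConfig,
    apply_mad_threshold,
    extract_training_segments,
    mad_stats,
    modified_zscore,
    preprocess_dataset,
    qualifies,
    trim,
)
from squigclass.signal_io import RawRead


# ---- independent brute-force oracle (sort-based, no numpy statistics) ----

def brute_median(values):
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def brute_mad(values):
    med = brute_median(values)
    return brute_median([abs(v - med) for v in values])


def brute_modified_z(values):
    med, mad = brute_median(values), brute_mad(values)
    return [0.6745 * (v - med) / mad for v in values]


def test_mad_stats_hand_examples():
    assert mad_stats(np.array([1, 2, 3, 4, 5])) == (3.0, 1.0)
    assert mad_stats(np.array([7.0, 7.0, 7.0])) == (7.0, 0.0)
    # outlier tolerance: deviations (2,1,0,1,97) -> median deviation 1
    assert mad_stats(np.array([1, 2, 3, 4, 100])) == (3.0, 1.0)


def test_modified_zscore_hand_example():
    z = modified_zscore(np.array([1, 2, 3, 4, 100]))
    assert z[-1] == pytest.approx(0.6745 * 97 / 1, abs=1e-9)
    assert z[2] == 0.0  # the median maps to 0


def test_modified_zscore_degenerate_raises():
    with pytest.raises(DegenerateSignalError):
        modified_zscore(np.array([5.0, 5.0, 5.0, 5.0]))
    with pytest.raises(ValueError):
        mad_stats(np.array([]))


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=40),
    st.floats(min_value=0.1, max_value=100.0),
    st.floats(min_value=-1e3, max_value=1e3),
)
def test_modified_zscore_matches_oracle_and_is_affine_invariant(ints, a, b):
    x = np.array(ints, dtype=float)
    med, mad = mad_stats(x)
    assert med == pytest.approx(brute_median(ints), abs=1e-9)
    assert mad == pytest.approx(brute_mad(ints), abs=1e-9)
    if mad == 0:
        return
    z = modified_zscore(x)
    assert np.allclose(z, brute_modified_z(ints), atol=1e-9)
    # invariance under positive affine maps
    assert np.allclose(modified_zscore(a * x + b), z, atol=1e-6)


def test_qualification_boundary():
    def read_of(n):
        return RawRead("r", np.zeros(n, dtype=np.int16), 8192, 10, 1400, 4000)

    cfg = PreprocessConfig()
    assert qualifies(read_of(4500), cfg)
    assert not qualifies(read_of(4499), cfg)
    assert not qualifies(read_of(0), cfg)


def test_trim_contract():
    assert len(trim(np.arange(4500), 1500)) == 3000
    assert np.array_equal(trim(np.arange(5), 0), np.arange(5))
    assert len(trim(np.arange(1500), 1500)) == 0
    with pytest.raises(ValueError):
        trim(np.arange(10), 11)


def test_training_segment_extraction_bounds_and_determinism():
    cfg = PreprocessConfig()
    sig = np.arange(6000.0)
    segs1 = extract_training_segments(sig, cfg, np.random.default_rng(42))
    segs2 = extract_training_segments(sig, cfg, np.random.default_rng(42))
    assert [s for s, _ in segs1] == [s for s, _ in segs2]
    assert len(segs1) == 4
    for start, window in segs1:
        assert 0 <= start <= 3000
        assert len(window) == 3000
        assert window[0] == sig[start]
    # forced single position
    forced = extract_training_segments(np.arange(3000.0), cfg, np.random.default_rng(0))
    assert all(s == 0 for s, _ in forced)
    # two valid positions only
    cfg1 = PreprocessConfig(segments_per_read_train=1)
    starts = {
        extract_training_segments(np.arange(3001.0), cfg1, np.random.default_rng(s))[0][0]
        for s in range(20)
    }
    assert starts <= {0, 1}


def test_mad_threshold_clamps_and_is_monotone():
    z = np.array([0.0, 66.0, -70.0])
    assert np.array_equal(apply_mad_threshold(z, 3), [0.0, 3.0, -3.0])
    small = np.array([0.5, -1.0, 2.0])
    assert np.array_equal(apply_mad_threshold(small, 3), small)
    rng = np.random.default_rng(1)
    v = rng.normal(0, 5, 500)
    clamped3 = np.abs(apply_mad_threshold(v, 3)) >= 3
    clamped10 = np.abs(apply_mad_threshold(v, 10)) >= 10
    # threshold 10 clamps a subset of what threshold 3 clamps
    assert np.all(clamped3[clamped10])


def _reads(n, n_samples, label=1, seed=0):
    rng = np.random.default_rng(seed)
    return [
        RawRead(f"x{seed}_{i}", rng.integers(-100, 2000, size=n_samples),
                8192, 10, 1400, 4000, label=label)
        for i in range(n)
    ]


def test_preprocess_dataset_counts_and_invariants():
    cfg = PreprocessConfig(rng_seed=5)
    reads = _reads(10, 5000, label=1, seed=1) + _reads(5, 3000, label=0, seed=2)
    X, y, prov, skipped = preprocess_dataset(reads, cfg, mode="train")
    assert X.shape == (40, 3000)  # 4 segments per qualified read
    assert len(skipped) == 5
    assert all("short read" in reason for _, reason in skipped)
    Xi, yi, _, skipped_i = preprocess_dataset(reads, cfg, mode="infer")
    assert Xi.shape == (10, 3000)  # first segment only
    assert len(skipped_i) == 5
    assert np.all(np.abs(X) <= cfg.mad_threshold)
    # determinism: same inputs + seed -> bit-identical matrix
    X2, _, _, _ = preprocess_dataset(reads, cfg, mode="train")
    assert np.array_equal(X, X2)


def test_preprocess_dataset_empty_raises():
    cfg = PreprocessConfig()
    with pytest.raises(EmptyDatasetError):
        preprocess_dataset(_reads(3, 100), cfg, mode="train")


def test_config_invariants():
    with pytest.raises(ValueError):
        PreprocessConfig(min_read_samples=1000)  # < trim + segment
    with pytest.raises(ValueError):
        PreprocessConfig(mad_threshold=0)
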