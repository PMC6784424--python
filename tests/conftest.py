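import numpy as np
import pytest

from pbrtqc import builtin_profiles, generate_stream


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def streams(profiles):
    """One synthetic six-month (121 working day) stream per analyte."""
    return {
        name: generate_stream(prof, n_days=121, seed=1 + i)
        for i, (name, prof) in enumerate(profiles.items())
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


# ---------------------------------------------------------------------------
# Independent oracles, deliberately written as slow direct computations so
# they share no code path with the engine they check.

def oracle_simple_ma(values, mask, n):
    """Trailing-window mean recomputed from scratch at every position."""
    out = []
    accepted = []
    last = float("nan")
    for v, ok in zip(values, mask):
        if ok:
            accepted.append(v)
            if len(accepted) >= n:
                last = sum(accepted[-n:]) / n
        out.append(last)
    return np.array(out)


def oracle_ewma_expansion(accepted_values, lam, init):
    """Explicit sum z_t = lam * sum (1-lam)^i x_(t-i) + (1-lam)^t z0."""
    out = np.empty(len(accepted_values))
    x = np.asarray(accepted_values, dtype=float)
    for t in range(1, len(x) + 1):
        weights = lam * (1.0 - lam) ** np.arange(t)
        out[t - 1] = float(np.dot(weights, x[t - 1 :: -1])) + (1.0 - lam) ** t * init
    return out


def oracle_replay_run(values, config, limits, injection_index, bias_percent, window):
    """One-result-at-a-time replay of a bias injection, pure Python.

    Returns (n_to_detection, n_accepted_to_detection), both None when
    censored within the window.
    """
    lo, hi = config.truncation.lower, config.truncation.upper

    def accept(v):
        return (lo is None or v >= lo) and (hi is None or v <= hi)

    factor = 1.0 + bias_percent / 100.0
    if config.algorithm == "simple":
        n = config.batch_size
        window_vals = []
        for v in values[:injection_index]:
            if accept(v):
                window_vals.append(v)
        state = window_vals[-n:]
    else:
        lam = config.weighting_factor
        if config.init_value == "population_mean":
            acc_all = [v for v in values if accept(v)]
            z = sum(acc_all) / len(acc_all)
        else:
            z = float(config.init_value)
        for v in values[:injection_index]:
            if accept(v):
                z = lam * v + (1.0 - lam) * z

    presented = 0
    accepted_count = 0
    for v in values[injection_index : injection_index + window]:
        biased = v * factor
        presented += 1
        if not accept(biased):
            continue
        accepted_count += 1
        if config.algorithm == "simple":
            state.append(biased)
            if len(state) < config.batch_size:
                continue
            ma = sum(state[-config.batch_size :]) / config.batch_size
        else:
            z = config.weighting_factor * biased + (1.0 - config.weighting_factor) * z
            ma = z
        if ma > limits.upper or ma < limits.lower:
            return presented, accepted_count
    return None, None
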