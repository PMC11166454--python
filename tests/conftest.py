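import numpy as np
import pytest

from hiberkit.synthetic import TelemetryGenSpec, generate_telemetry


@pytest.fixture(scope="session")
def small_cohort():
    """3 animals x 3 cycles, fixed seed; shared across tests (read-only)."""
    spec = TelemetryGenSpec(n_animals=3, n_cycles=3, seed=11)
    traces, truth = generate_telemetry(spec)
    return spec, traces, truth


@pytest.fixture(scope="session")
def single_bout():
    """One animal, one full T-A cycle."""
    spec = TelemetryGenSpec(n_animals=1, n_cycles=1, seed=5)
    traces, truth = generate_telemetry(spec)
    aid = next(iter(traces))
    return spec, traces[aid], truth.animals[aid]


def perm_maxt_pvalues(samples, n_perm=100_000, seed=0):
    """Permutation null of max |t| over comparisons against the control
    (first sample): independent oracle for Dunnett-adjusted p-values."""
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in samples]
    n = sum(sizes)
    bounds = np.cumsum([0] + sizes)
    k = len(samples)

    def tstats(stacked):
        # stacked: (m, n) array of permuted rows
        groups = [stacked[:, bounds[j]:bounds[j + 1]] for j in range(k)]
        means = [g.mean(axis=1) for g in groups]
        sse = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means))
        s2 = sse / (n - k)
        ts = [
            (means[j] - means[0]) / np.sqrt(s2 * (1 / sizes[j] + 1 / sizes[0]))
            for j in range(1, k)
        ]
        return np.column_stack(ts)

    all_v = np.concatenate(samples)
    t_obs = tstats(all_v[None, :])[0]
    maxs = np.empty(n_perm)
    chunk = 2000
    for lo in range(0, n_perm, chunk):
        m = min(chunk, n_perm - lo)
        order = np.argsort(rng.random((m, n)), axis=1)
        maxs[lo:lo + m] = np.abs(tstats(all_v[order])).max(axis=1)
    return t_obs, np.array([(np.sum(maxs >= abs(t)) + 1) / (n_perm + 1) for t in t_obs])
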