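import pytest

import negstore as ns


@pytest.fixture(scope="session")
def fig1_data(tmp_path_factory):
    """The worked 7x11 cohort, with its files on disk."""
    out = tmp_path_factory.mktemp("fig1")
    return ns.fig1_fixture(out_dir=str(out))


@pytest.fixture(scope="session")
def fig1_backends(fig1_data):
    """All three backends loaded from the fixture manifest (full ingest path)."""
    backends = {k: ns.open_backend(k) for k in ("nsm", "fsm", "blsm")}
    ns.load_cohort(fig1_data.manifest_path, backends.values())
    for be in backends.values():
        be.create_indexes()
    yield backends
    for be in backends.values():
        be.close()


@pytest.fixture(scope="session")
def small_cohort():
    """A small random cohort loaded directly (no file I/O), with its truth."""
    spec = ns.CohortSpec(
        n_samples=12,
        universe_bp=20_000,
        kits=(
            ns.KitSpec("kitA", 0.05, 100),
            ns.KitSpec("kitB", 0.08, 100),
            ns.KitSpec("kitC", 0.06, 100),
        ),
        variant_rate=0.01,
        missing_rate=0.03,
        seed=11,
    )
    data = ns.generate_cohort(spec)
    backends = {k: ns.open_backend(k) for k in ("nsm", "fsm", "blsm")}
    ns.load_cohort_into(data, backends.values())
    for be in backends.values():
        be.create_indexes()
    yield data, backends
    for be in backends.values():
        be.close()


def brute_force_runs(states):
    """Independent run scanner: linear walk accumulating (start, end, state)."""
    runs = []
    for i, s in enumerate(states):
        if runs and runs[-1][2] == s and runs[-1][1] == i:
            runs[-1] = (runs[-1][0], i + 1, s)
        else:
            runs.append((i, i + 1, s))
    return runs
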