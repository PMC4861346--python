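import pytest

import pumpleak as pl


@pytest.fixture(scope="session")
def reference_datap():
    """Reference DATAP parameter set (RPMI + 5 mM LiCl)."""
    return pl.fixtures.reference()


@pytest.fixture(scope="session")
def reference_run(reference_datap):
    """Fixed 500-min reference run (the original report schedule:
    dt 0.1 min, one row per hp = 500 steps, 10 rows)."""
    system = pl.initialize_run(reference_datap, balance_tol=None, max_outputs=10)
    return pl.run(system)


@pytest.fixture(scope="session")
def balanced_cell(reference_run):
    return reference_run.cell


@pytest.fixture(scope="session")
def flux_table(reference_run):
    t = reference_run
    return pl.unidirectional_decomposition(t.cell, t.medium, t.params,
                                           t.potential.u)


@pytest.fixture(scope="session")
def converged_run(reference_datap):
    """Tightly converged balanced state (derivatives < 1e-6 mM/min) for
    fixed-point and flux-closure invariants."""
    system = pl.initialize_run(reference_datap, balance_tol=1e-6, max_outputs=300)
    traj = pl.run(system)
    assert traj.balanced
    return traj


@pytest.fixture(scope="session")
def lifree_run(reference_datap):
    """Balanced state of the same cell in Li-free RPMI (the 'normal'
    background used for 22Na tracer work)."""
    datap = reference_datap.replace(l0=0, cl0=116, kv=1.0, l=0)
    system = pl.initialize_run(datap, balance_tol=0.001)
    traj = pl.run(system)
    assert traj.balanced
    return traj
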