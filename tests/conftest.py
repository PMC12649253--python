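import numpy as np
import pandas as pd
import pytest

from depmsm.adalasso import fit_initial
from depmsm.cohort import default_cohort_spec, generate_covariates, simulate_state_paths
from depmsm.design import StackedDesign, TransitionStructure, build_transition_records


@pytest.fixture(scope="session")
def demo_cohort():
    """A small default-condition cohort shared across tests (seeded)."""
    spec = default_cohort_spec(n_subjects=800, seed=5)
    cov = generate_covariates(spec)
    sim = simulate_state_paths(cov, spec)
    return spec, cov, sim


@pytest.fixture(scope="session")
def demo_design(demo_cohort):
    _, _, sim = demo_cohort
    return build_transition_records(sim.sequences, sim.model.reset_index())


@pytest.fixture(scope="session")
def demo_initial(demo_design):
    return fit_initial(demo_design)


def toy_design(rows, covariate_names=("x",), paths=("12",)):
    """Build a StackedDesign directly from (subject, path, entry, exit, status,
    *covariates) tuples — used by the hand-checkable likelihood oracles."""
    groups = tuple((p,) for p in paths)
    structure = TransitionStructure(paths=tuple(paths), coefficient_groups=groups)
    table = pd.DataFrame(
        rows, columns=["subject_id", "path", "entry", "exit", "status", *covariate_names]
    )
    table.insert(2, "group", table["path"])
    return StackedDesign(table, tuple(covariate_names), structure)
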