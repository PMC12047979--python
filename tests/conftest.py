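import numpy as np
import pytest

from condensate_spt.simulate import (
    Scene,
    Nanodomain,
    SimParams,
    simulate_trajectories,
    simulate_brownian_control,
)


@pytest.fixture(scope="session")
def brownian_control():
    """1000 pure random-walk trajectories at the standard study conditions."""
    return simulate_brownian_control(n_trajectories=1000, seed=11)


@pytest.fixture(scope="session")
def nanodomain_scene():
    return Scene(
        condensate_center=(2.0, 2.0),
        condensate_radius=1.5,
        nanodomains=[
            Nanodomain((1.4, 1.6), 0.12, escape_prob=0.02),
            Nanodomain((2.5, 2.4), 0.10, escape_prob=0.02),
            Nanodomain((2.0, 2.9), 0.15, escape_prob=0.02),
        ],
    )


@pytest.fixture(scope="session")
def mixture_scene():
    """Large condensate: normal molecules rarely feel the boundary."""
    return Scene(
        condensate_center=(5.0, 5.0),
        condensate_radius=5.0,
        nanodomains=[
            Nanodomain((4.2, 4.4), 0.12, escape_prob=0.02),
            Nanodomain((5.6, 5.4), 0.10, escape_prob=0.02),
            Nanodomain((5.0, 6.2), 0.15, escape_prob=0.02),
        ],
    )


@pytest.fixture(scope="session")
def three_class_set(mixture_scene):
    """Labeled mixture of immobile / confined / normal trajectories.

    Track lengths >= 20 localizations so each class is identifiable in
    principle: the alpha fit of a 5-localization track has essentially
    no statistical power, which is a property of the estimator rather
    than of the classifier under test.
    """
    params = SimParams(
        D_free=1.0,
        D_confined=0.2,
        p_immobile=0.2,
        p_confined=0.4,
        n_trajectories=400,
        mean_length=30.0,
        min_length=20,
        seed=7,
    )
    return simulate_trajectories(mixture_scene, params)
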