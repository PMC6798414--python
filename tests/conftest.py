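import numpy as np
import pytest

from camrad.synthetic import generate_kinetic_curves, generate_mixture_image

TIMEPOINTS = np.arange(0.0, 8.5, 1.0)  # minutes, T = 9


@pytest.fixture(scope="session")
def curves3():
    return generate_kinetic_curves(3, TIMEPOINTS, seed=2)


@pytest.fixture(scope="session")
def tumour_noise_free(curves3):
    return generate_mixture_image(curves3, shape=(12, 12, 6), corner_fraction=0.05,
                                  noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def tumour_noisy(curves3):
    sigma = 0.02 * curves3.curves.max()
    return generate_mixture_image(curves3, shape=(12, 12, 6), corner_fraction=0.05,
                                  noise_sigma=sigma, seed=3)


def align_permutation(estimated, truth):
    """Permutation of truth rows maximising summed cosine with estimated rows."""
    from itertools import permutations

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    J = estimated.shape[0]
    return max(permutations(range(J)),
               key=lambda p: sum(cos(estimated[i], truth[p[i]]) for i in range(J)))
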