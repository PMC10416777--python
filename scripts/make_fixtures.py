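"""Regenerate the model/tree fixtures bundled with the package.

All fixtures are synthetic and fully determined by the seeds below:

* poisson.dat          — uniform exchangeabilities and frequencies
* surrogate_sim.dat    — the surrogate simulation model: log-normal
                         exchangeabilities (sigma 1.6, the spread of
                         empirical amino-acid matrices) and a moderately
                         uneven composition
* surrogate_near.dat   — comparison fixture close to the simulation model
                         (convex blend), playing the role of a related
                         empirical model
* surrogate_far.dat    — independent, flatter draw (sigma 0.5), playing the
                         role of a distant general-purpose empirical model:
                         averaged models are flatter than any data-specific
                         truth, which is what makes them underestimate
                         multiple hits and infer shorter trees
* surrogate_tree.nwk   — 26-taxon unrooted binary tree, total length 7.74
"""

from pathlib import Path

import numpy as np

from aamodelkit.alphabet import N_PAIRS, N_STATES
from aamodelkit.model import SubstitutionModel, poisson_model, write_model_file
from aamodelkit.synthetic import random_tree

OUT = Path(__file__).resolve().parent.parent / "src" / "aamodelkit" / "data"


def lognormal_model(seed: int, sigma: float = 1.6, comp_conc: float = 20.0, name: str = "surrogate") -> SubstitutionModel:
    rng = np.random.default_rng(seed)
    ex = np.exp(rng.normal(0.0, sigma, N_PAIRS))
    comp = rng.dirichlet(np.full(N_STATES, comp_conc))
    return SubstitutionModel(ex / ex.sum(), comp, alpha=0.8, ncat=4, name=name)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    write_model_file(poisson_model(), OUT / "poisson.dat")

    sim = lognormal_model(20230808, name="surrogate_sim")
    write_model_file(sim, OUT / "surrogate_sim.dat")

    other = lognormal_model(77, name="blendsrc")
    near_ex = 0.65 * sim.exchangeabilities + 0.35 * other.exchangeabilities
    near_comp = 0.65 * sim.composition + 0.35 * other.composition
    near = SubstitutionModel(near_ex, near_comp, alpha=0.8, name="surrogate_near")
    write_model_file(near, OUT / "surrogate_near.dat")

    far = lognormal_model(4099, sigma=0.5, comp_conc=40.0, name="surrogate_far")
    write_model_file(far, OUT / "surrogate_far.dat")

    tree = random_tree(26, 7.74, seed=2026)
    tree.write(OUT / "surrogate_tree.nwk")

    d_near = np.abs(near.exchangeabilities - sim.exchangeabilities).sum()
    d_far = np.abs(far.exchangeabilities - sim.exchangeabilities).sum()
    print(f"L1(near, sim) = {d_near:.4f}; L1(far, sim) = {d_far:.4f}")
    assert d_near < d_far


if __name__ == "__main__":
    main()
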