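import numpy as np
import pytest

from pairomega import (
    STANDARD_CODE,
    CodonFrequencies,
    GammaPrior,
    PairAlignment,
)
from pairomega.simulator import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def fequal() -> CodonFrequencies:
    return CodonFrequencies.equal()


@pytest.fixture(scope="session")
def prior() -> GammaPrior:
    return GammaPrior()


def random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [STANDARD_CODE.sense_codons[k] for k in rng.integers(0, 61, n)]


@pytest.fixture(scope="session")
def case_fixtures() -> dict[str, PairAlignment]:
    """Small alignments spanning the five qualitative data regimes:

    I   both synonymous and nonsynonymous differences (informative),
    II  identical sequences,
    III synonymous differences only,
    IV  nonsynonymous differences only,
    V   essentially random sequence pairs.
    """
    rng = np.random.default_rng(2024)
    out: dict[str, PairAlignment] = {}
    out["caseI"] = simulate_pair(SimConfig(L_c=100, t=0.3, omega=0.3, kappa=2, seed=11))
    cod = random_codons(rng, 100)
    out["caseII"] = PairAlignment(("a", "b"), list(cod), list(cod))
    # TTT->TTC is synonymous (Phe), TTT->GTT nonsynonymous (Phe->Val)
    base = ["TTT"] * 20 + random_codons(rng, 80)
    out["caseIII"] = PairAlignment(("a", "b"), list(base), ["TTC"] * 10 + base[10:])
    base = ["TTT"] * 20 + random_codons(rng, 80)
    out["caseIV"] = PairAlignment(("a", "b"), list(base), ["GTT"] * 10 + base[10:])
    out["caseV"] = PairAlignment(
        ("a", "b"), random_codons(rng, 100), random_codons(rng, 100)
    )
    return out
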