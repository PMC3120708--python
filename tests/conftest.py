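import numpy as np
import pytest

from pipesites.io_formats import InteractionDB, Protein
from pipesites.landscape import Landscape


@pytest.fixture
def toy_proteome() -> dict[str, Protein]:
    return {
        pid: Protein(pid, seq)
        for pid, seq in [
            ("A", "MKLV"),
            ("B", "AAGW"),
            ("X", "QMKL"),
            ("Y", "GAAG"),
        ]
    }


@pytest.fixture
def toy_db(toy_proteome) -> InteractionDB:
    return InteractionDB(proteome=toy_proteome, pairs={("X", "Y")})


def make_landscape(H, w: int = 1, id_a: str = "A", id_b: str = "B") -> Landscape:
    return Landscape(id_a, id_b, w, np.asarray(H, dtype=np.int64))


def random_proteome(rng: np.random.Generator, n: int, max_len: int = 30,
                    alphabet: str = "ACDG") -> dict[str, Protein]:
    """Small random proteome over a reduced alphabet (forces window collisions)."""
    out = {}
    for idx in range(n):
        length = int(rng.integers(5, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=length))
        out[f"P{idx}"] = Protein(f"P{idx}", seq)
    return out


def brute_force_landscape(a: Protein, b: Protein, db: InteractionDB, w: int) -> np.ndarray:
    """Triple-loop oracle: count oriented pairs whose proteins contain both windows."""
    n_a, n_b = a.length - w + 1, b.length - w + 1
    H = np.zeros((max(n_a, 0), max(n_b, 0)), dtype=np.int64)
    for x, y in db.oriented_pairs():
        for i in range(n_a):
            if a.sequence[i:i + w] not in x.sequence:
                continue
            for j in range(n_b):
                if b.sequence[j:j + w] in y.sequence:
                    H[i, j] += 1
    return H
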