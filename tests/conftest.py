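import numpy as np
import pytest

from kennelquant.pedigree import Pedigree, PedigreeRecord, compute_inbreeding
from kennelquant.simulate import SimConfig, simulate_pedigree


def make_pedigree(rows):
    """rows: (id, sire, dam) or (id, sire, dam, sex) tuples, topologically ordered."""
    recs = []
    for row in rows:
        rid, sire, dam = row[:3]
        sex = row[3] if len(row) > 3 else "unknown"
        recs.append(PedigreeRecord(id=rid, sire_id=sire, dam_id=dam, sex=sex))
    return Pedigree(recs)


@pytest.fixture
def trio():
    """Sire, dam and their offspring."""
    return make_pedigree([("S", None, None, "male"), ("D", None, None, "female"), ("O", "S", "D")])


@pytest.fixture
def fullsib_mating():
    """Offspring of a full-sib mating: f = 0.25."""
    return make_pedigree(
        [
            ("GS", None, None, "male"),
            ("GD", None, None, "female"),
            ("S", "GS", "GD", "male"),
            ("D", "GS", "GD", "female"),
            ("X", "S", "D"),
        ]
    )


def random_pedigree(seed: int, size: int = 120) -> Pedigree:
    cfg = SimConfig(
        n_founders=max(size // 5, 6),
        n_generations=3,
        generation_size=max(size // 4, 6),
        seed=seed,
    )
    return compute_inbreeding(simulate_pedigree(cfg))
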