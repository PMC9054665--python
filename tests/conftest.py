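import numpy as np
import pytest
from hypothesis import settings

from promotif import PromoterRecord, PromoterUniverse

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_record(seq: str, start_offset: int = -500, gene_id: str = "G1") -> PromoterRecord:
    return PromoterRecord(gene_id=gene_id, sequence=seq, start_offset=start_offset)


def make_universe(seqs, start_offset: int = -500) -> PromoterUniverse:
    return PromoterUniverse(
        records=tuple(
            PromoterRecord(gene_id=f"G{i + 1}", sequence=s, start_offset=start_offset)
            for i, s in enumerate(seqs)
        )
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
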