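import numpy as np
import pytest

from pcdhkit import LabeledMSA, SeqLabel

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_msa(seqs, species=None, isoforms=None, subfamily="fam"):
    """Labelled alignment from plain sequence strings."""
    n = len(seqs)
    species = species or [f"sp{i}" for i in range(n)]
    isoforms = isoforms or [f"iso{i}" for i in range(n)]
    labels = [
        SeqLabel(species=s, isoform=i, subfamily=subfamily, header=f"{s}|{i}|{subfamily}")
        for s, i in zip(species, isoforms)
    ]
    return LabeledMSA(sequences=list(seqs), labels=labels)


def random_labeled_msa(rng, n_species=None, n_isoforms=None, L=None, gap_frac=0.1):
    """Random ortholog/paralog-labelled alignment for oracle comparisons."""
    n_species = n_species or int(rng.integers(2, 5))
    n_isoforms = n_isoforms or int(rng.integers(2, 5))
    L = L or int(rng.integers(3, 31))
    while n_species * n_isoforms > 20:
        n_species = max(2, n_species - 1)
        n_isoforms = max(2, n_isoforms - 1)
    seqs, species, isoforms = [], [], []
    alphabet = np.array(list(AA + "-"))
    probs = np.full(21, (1 - gap_frac) / 20)
    probs[20] = gap_frac
    for iso in range(n_isoforms):
        for sp in range(n_species):
            codes = rng.choice(21, size=L, p=probs)
            seqs.append("".join(alphabet[codes]))
            species.append(f"sp{sp}")
            isoforms.append(f"iso{iso}")
    return make_msa(seqs, species=species, isoforms=isoforms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
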