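import numpy as np
import pytest

from structppi.synthetic import FixtureSpec, make_complex


@pytest.fixture(scope="session")
def truth1():
    """One seeded two-helix complex with ground truth, shared across tests."""
    return make_complex(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def complex_bank():
    """Twenty seeded complexes for the statistical acceptance properties."""
    return {s: make_complex(FixtureSpec(seed=s)) for s in range(1, 21)}


def interface_ca_rmsd(pred, truth):
    """CA RMSD of a predicted pose to the native complex over interface residues."""
    native = {(r.id.chain_id, r.id.author_number): r.ca.position
              for ch in truth.structure.chains.values() for r in ch.residues}
    posed = {(r.id.chain_id, r.id.author_number): r.ca.position
             for ch in pred.pose.chains.values() for r in ch.residues}
    ids = [(r.id.chain_id, r.id.author_number)
           for side in (truth.template.side_a, truth.template.side_b)
           for r in side.ordered_residues()]
    P = np.array([posed[i] for i in ids])
    Q = np.array([native[i] for i in ids])
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
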