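import numpy as np
import pytest

from plifscreen.plif import Pose, PoseContactTable


@pytest.fixture
def small_vocab():
    return ("LEU70", "VAL75", "LEU78", "LEU129", "ASP156", "LEU157")


def random_contact_table(rng, vocab, n_poses=None, compound_id="c"):
    """Random pose-contact table for oracle checks (<= 10 poses x vocab)."""
    n_poses = n_poses or int(rng.integers(4, 11))
    scores = rng.normal(50, 10, size=n_poses)
    poses = []
    for i in range(n_poses):
        on = [r for r in vocab if rng.random() < 0.4]
        poses.append(
            Pose(
                pose_index=i + 1,
                score=float(scores[i]),
                contacts=frozenset((r, "hydrophobic") for r in on),
            )
        )
    return PoseContactTable(compound_id=compound_id, poses=poses)


@pytest.fixture
def contact_table_factory():
    return random_contact_table


def brute_force_robust_bits(table, top_n, min_poses, vocab):
    """Independent oracle: count contacts per residue over the top-n poses."""
    ranked = sorted(table.poses, key=lambda p: (-p.score, p.pose_index))[:top_n]
    bits = []
    for residue in vocab:
        count = sum(
            1 for pose in ranked if any(res == residue for res, _ in pose.contacts)
        )
        bits.append(1 if count >= min_poses else 0)
    return np.array(bits, dtype=np.uint8)
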