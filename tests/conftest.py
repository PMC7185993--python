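import numpy as np
import pytest

from gtacore.alignment import AlignedSequenceSet, CoreAnnotation, SequenceRecord


def make_alignment(core_states, families=None, inserts=None, ids=None):
    """Build an AlignedSequenceSet from a list of core-state strings."""
    n = len(core_states[0])
    records = []
    for i, states in enumerate(core_states):
        records.append(
            SequenceRecord(
                id=(ids[i] if ids else f"seq{i + 1}"),
                core_states=states,
                family_label=(families[i] if families else None),
                inserts=dict(inserts[i]) if inserts else {},
            )
        )
    return AlignedSequenceSet(records, n)


def make_annotation(n_columns, hv1, hv2, hv3):
    ss = ["loop"] * n_columns
    motif = ["none"] * n_columns
    hv = ["none"] * n_columns
    hv[hv1 - 1], hv[hv2 - 1], hv[hv3 - 1] = "HV1", "HV2", "HV3"
    return CoreAnnotation(ss_element=ss, motif_tag=motif, hv_anchor=hv)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
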