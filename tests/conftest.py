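"""Shared fixtures: the desk-scale recovery studies, run once per session.

The two training studies are the expensive parts of the suite (one to a few
minutes each on one CPU), so they are session-scoped and shared by every
test that needs a trained model.  The study conditions themselves live in
``alnvec.protocols`` and are fixed; everything is seeded and deterministic.
"""

import pytest

from alnvec.protocols import (
    run_alignment_recovery,
    run_retrieval_pipeline,
    run_tmvec_recovery,
)


@pytest.fixture(scope="session")
def tmvec_study():
    """Twin encoder trained on the ~500-pair synthetic similarity study."""
    return run_tmvec_recovery(seed=0)


@pytest.fixture(scope="session")
def align_study():
    """Aligner trained on 300 filtered synthetic alignments."""
    return run_alignment_recovery(seed=0)


@pytest.fixture(scope="session")
def retrieval_study(tmvec_study):
    """Fold-corpus retrieval with the trained encoder."""
    return run_retrieval_pipeline(tmvec_study, seed=0)
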