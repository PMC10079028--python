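"""Shared fixtures: one calibrated synthetic corpus per session.

The corpus emulates the study design — 7 disposition-matched dyads per
group — with 20 task dialogues per dyad so every group x stage cell holds
well over 2000 floor transfers and cell means are estimated with a
Monte-Carlo SE well inside the acceptance tolerances.
"""

from __future__ import annotations

import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from turntaking import (  # noqa: E402
    analyse_corpus,
    default_params,
    simulate_corpus,
    transfers_frame,
    within_overlap_frame,
)

CORPUS_SEED = 20230923


@pytest.fixture(scope="session")
def paper_params():
    return default_params()


@pytest.fixture(scope="session")
def calibrated_corpus(paper_params):
    return simulate_corpus(
        paper_params, n_dyads_per_group=7, dialogues_per_dyad=20, seed=CORPUS_SEED
    )


@pytest.fixture(scope="session")
def analysed_corpus(calibrated_corpus):
    return analyse_corpus([record for record, _truth in calibrated_corpus])


@pytest.fixture(scope="session")
def transfers(analysed_corpus):
    return transfers_frame(analysed_corpus)


@pytest.fixture(scope="session")
def within_events(analysed_corpus):
    return within_overlap_frame(analysed_corpus)
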