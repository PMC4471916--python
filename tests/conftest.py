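from __future__ import annotations

from datetime import date, time

import numpy as np
import pandas as pd
import pytest

from songprov.feature_model import RESPONSE, SONG_MEASURES
from songprov.feeding import events_to_visits, group_rates, session_rates, summarize_male
from songprov.song_corpus import SongRecord, SongSequence, compute_repertoire
from songprov.song_network import network_metrics
from songprov.synthetic_data import SimulationConfig, simulate_study


def make_sequence(types, categories=None, male_id="M01"):
    """Build a SongSequence from a list of type labels (default: all whistle)."""
    if categories is None:
        categories = ["whistle"] * len(types)
    records = tuple(
        SongRecord(male_id=male_id, position=i + 1, song_type=t, category=c)
        for i, (t, c) in enumerate(zip(types, categories))
    )
    return SongSequence(male_id=male_id, records=records)


def small_sim_config(seed=0, n_males=8, **overrides) -> SimulationConfig:
    """A fast simulation config: small repertoires, short sequences, 2 days."""
    defaults = dict(
        seed=seed,
        n_males=n_males,
        sequence_length=200,
        repertoire_mean=40.0,
        repertoire_sd=8.0,
        whistle_mean=8.0,
        whistle_sd=2.0,
        trill_mean=6.0,
        trill_sd=2.0,
        buzz_mean=3.0,
        buzz_sd=1.0,
        days_recorded=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def study_feature_table(study) -> pd.DataFrame:
    """Per-male feature table (nine song measures + covariates + response)."""
    window = study.config.sequence_length
    rows = {}
    for seq in study.sequences:
        rep = compute_repertoire(seq, window=window)
        met = network_metrics(seq)
        rows[seq.male_id] = {
            "repertoire_size": rep.repertoire_size,
            "whistle_repertoire": rep.whistle_repertoire,
            "whistle_occurrence": rep.whistle_occurrence,
            "trill_repertoire": rep.trill_repertoire,
            "trill_occurrence": rep.trill_occurrence,
            "buzz_repertoire": rep.buzz_repertoire,
            "buzz_occurrence": rep.buzz_occurrence,
            "average_shortest_path": met.average_shortest_path,
            "transitivity": met.transitivity,
        }
    grouped = group_rates(session_rates(events_to_visits(study.events)))
    meta = study.metadata.set_index("male_id")
    recs = []
    for male_id, meas in sorted(rows.items()):
        recs.append(
            {
                "male_id": male_id,
                **meas,
                "n_hatchlings": float(meta.loc[male_id, "n_hatchlings"]),
                "year": meta.loc[male_id, "year"],
                RESPONSE: summarize_male(grouped[male_id], male_id=male_id).median_rate,
            }
        )
    return pd.DataFrame(recs).set_index("male_id")


@pytest.fixture(scope="session")
def default_study():
    """One full-size default synthetic study, shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_feature_table(default_study):
    return study_feature_table(default_study)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
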