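"""Shared fixtures: tiny hand-built tables and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pnu.exposure import ExposureSetDefinition, ExposureSets
from pnu.simulate import SimulationConfig, generate_population

D0 = pd.Timestamp("2000-01-01")


def day(n) -> pd.Timestamp:
    """Whole-day offset from the conventional origin 2000-01-01."""
    return D0 + pd.Timedelta(days=int(n))


def make_prescriptions(rows) -> pd.DataFrame:
    """Rows of (patient_id, drug_class, day_offset, supply_days)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "drug_class": drug,
                "issue_date": day(offset),
                "supply_days": supply,
            }
            for pid, drug, offset, supply in rows
        ]
    )


def make_members(rows) -> pd.DataFrame:
    """Rows of (patient_id, role, entry_day, index_day_or_None, k, tse, year,
    switch_day_or_None) -> cohort membership table."""
    recs = []
    for pid, role, entry, index, k, tse, year, switch in rows:
        recs.append(
            {
                "patient_id": pid,
                "role": role,
                "entry_date": day(entry),
                "index_date": day(index) if index is not None else pd.NaT,
                "prior_comparator_rx": k,
                "time_since_entry_days": tse,
                "calendar_year": year,
                "switch_date": day(switch) if switch is not None else pd.NaT,
            }
        )
    return pd.DataFrame(recs)


def make_sets(set_specs, kind: str = "prescription") -> ExposureSets:
    """Hand-built ExposureSets.

    ``set_specs``: list of (set_id, treated_dict, [candidate_dicts]) where
    treated_dict has patient_id/role/index_day/k/tse/year and candidates have
    patient_id/index_day/k/tse/year.
    """
    treated_rows, cand_rows = [], []
    for set_id, tr, cands in set_specs:
        treated_rows.append(
            {
                "set_id": set_id,
                "patient_id": tr["patient_id"],
                "treated_role": tr.get("role", "incident_study"),
                "index_date": day(tr.get("index_day", 0)),
                "prior_comparator_rx": tr.get("k", 0),
                "time_since_entry_days": tr.get("tse", 0),
                "calendar_year": tr.get("year", 2000),
                "n_candidates": len(cands),
            }
        )
        for c in cands:
            cand_rows.append(
                {
                    "set_id": set_id,
                    "candidate_patient_id": c["patient_id"],
                    "candidate_index_date": day(c.get("index_day", 0)),
                    "prior_comparator_rx": c.get("k", 0),
                    "time_since_entry_days": c.get("tse", 0),
                    "calendar_year": c.get("year", 2000),
                }
            )
    treated = pd.DataFrame(treated_rows)
    candidates = pd.DataFrame(
        cand_rows,
        columns=[
            "set_id",
            "candidate_patient_id",
            "candidate_index_date",
            "prior_comparator_rx",
            "time_since_entry_days",
            "calendar_year",
        ],
    )
    return ExposureSets(treated, candidates, ExposureSetDefinition(kind))


@pytest.fixture(scope="session")
def small_dataset():
    """A 1500-patient simulated dataset with moderate confounding."""
    cfg = SimulationConfig(
        n_patients=1500,
        choice_log_odds={"age": 0.4, "comorbidity": 0.5},
        confounder_log_hrs={"age": 0.4, "comorbidity": 0.5},
        seed=424242,
    )
    return cfg, generate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
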