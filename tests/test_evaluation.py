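"""LOOCV protocol, ROC/AUC construction, aggregation, and sweeps."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import rankdata

from rwdisenh import (
    BipartiteAssociations,
    AssociationTable,
    WeightedNetwork,
    aggregate,
    compare_mean_aucs,
    entity_aucs,
    loocv,
    parameter_sweep,
    roc_and_auc,
)
from rwdisenh.evaluation import LoocvRecord


def mann_whitney_auc(records) -> float:
    """Independent oracle: pooled pairwise comparisons with 0.5 tie credit.

    Lower rank is better; the statistic is the probability that a random
    held-out node outranks a random candidate.
    """
    pos = [r.rank for r in records]
    neg = np.concatenate([r.candidate_ranks for r in records])
    wins = 0.0
    for p in pos:
        wins += (p < neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))


def _record(entity, rank, n_candidates):
    grid = np.delete(np.arange(1.0, n_candidates + 2), int(rank) - 1)
    return LoocvRecord(entity, f"s{rank}", float(rank), n_candidates, grid)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_perfect_ranking_auc_one():
    records = [_record("d", 1, 100) for _ in range(3)]
    assert roc_and_auc(records).auc == pytest.approx(1.0)


def test_worst_ranking_auc_near_zero():
    records = [_record("d", 101, 100)]
    assert roc_and_auc(records).auc <= 1 / 100


@pytest.mark.parametrize("rank, n", [(1, 9), (4, 9), (10, 9), (7, 50)])
def test_single_record_rank_identity(rank, n):
    """One trial with rank r among N = |C|+1 items has AUC (N-r)/(N-1)."""
    curve = roc_and_auc([_record("d", rank, n)])
    assert curve.auc == pytest.approx((n + 1 - rank) / n, abs=1e-15)


def test_roc_monotone_and_endpoints():
    rng = np.random.default_rng(0)
    records = [
        _record("d", int(rng.integers(1, 12)), 11) for _ in range(6)
    ]
    curve = roc_and_auc(records)
    assert np.all(np.diff(curve.fpr) >= 0)
    assert np.all(np.diff(curve.tpr) >= 0)
    assert curve.fpr[0] == curve.tpr[0] == 0.0
    assert curve.fpr[-1] == curve.tpr[-1] == 1.0


@pytest.mark.parametrize("seed", range(30))
def test_auc_equals_mann_whitney_with_ties(seed):
    """Trapezoidal AUC over the threshold sweep equals the average-rank
    Mann-Whitney statistic exactly, including tied scores."""
    rng = np.random.default_rng(seed)
    records = []
    for t in range(int(rng.integers(1, 5))):
        n_cand = int(rng.integers(2, 15))
        # coarse integer scores force plenty of ties
        scores = rng.integers(0, 4, size=n_cand + 1).astype(float)
        ranks = rankdata(-scores, method="average")
        records.append(
            LoocvRecord("d", f"h{t}", float(ranks[0]), n_cand, ranks[1:])
        )
    curve = roc_and_auc(records)
    assert curve.auc == pytest.approx(mann_whitney_auc(records), abs=1e-12)


def test_roc_requires_records():
    with pytest.raises(ValueError):
        roc_and_auc([])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_two_point():
    s = aggregate({"a": 0.8, "b": 1.0})
    assert s.mean == pytest.approx(0.9)
    assert s.se == pytest.approx(0.1)
    assert s.n == 2


def test_aggregate_single_entity_has_no_se():
    s = aggregate({"a": 0.7})
    assert s.mean == 0.7 and s.se is None and s.n == 1


def test_aggregate_identical_values_zero_se():
    s = aggregate({"a": 0.6, "b": 0.6, "c": 0.6})
    assert s.se == 0.0


def test_welch_comparison_runs():
    t, p = compare_mean_aucs([0.9, 0.95, 0.92], [0.5, 0.55, 0.52])
    assert p < 0.01 and t > 0


# ---------------------------------------------------------------------------
# LOOCV protocol
# ---------------------------------------------------------------------------


def _small_world():
    """Enhancer path e1-e2-e3-e4, two linked diseases, hand associations."""
    enh = WeightedNetwork.from_edges(
        ("e1", "e2", "e3", "e4"),
        [("e1", "e2", 1.0), ("e2", "e3", 1.0), ("e3", "e4", 1.0)],
    )
    dis = WeightedNetwork.from_edges(("D1", "D2"), [("D1", "D2", 1.0)])
    assoc = AssociationTable((("D1", "e1"), ("D1", "e2"), ("D2", "e4")))
    return enh, dis, assoc


def test_homogeneous_two_known_gives_two_records():
    enh, dis, assoc = _small_world()
    res = loocv(
        "rwdisenh",
        enhancer_network=enh,
        disease_network=dis,
        associations=assoc,
        view="enhancer",
    )
    d1 = [r for r in res.records if r.entity == "D1"]
    assert len(d1) == 2
    assert {r.held_out for r in d1} == {"e1", "e2"}
    # D2 has one association: skipped with a reason, never silently
    assert "D2" in res.skipped and "at least 2" in res.skipped["D2"]


def test_hetero_covers_single_association_entities():
    enh, dis, assoc = _small_world()
    res = loocv(
        "rwdisenh",
        enhancer_network=enh,
        disease_network=dis,
        associations=assoc,
        view="hetero",
    )
    assert [r.entity for r in res.records].count("D2") == 1
    assert not res.skipped


def test_unique_neighbor_recovered_at_rank_one():
    """Held-out enhancer that is the seed's only neighbor ranks first."""
    enh = WeightedNetwork.from_edges(
        ("e1", "e2", "e3", "e4"), [("e1", "e2", 1.0), ("e3", "e4", 1.0)]
    )
    dis = WeightedNetwork.from_edges(("D1", "D2"), [("D1", "D2", 1.0)])
    assoc = AssociationTable((("D1", "e1"), ("D1", "e2")))
    res = loocv(
        "rwdisenh",
        enhancer_network=enh,
        disease_network=dis,
        associations=assoc,
        view="enhancer",
    )
    rec = next(r for r in res.records if r.held_out == "e2")
    assert rec.rank == 1.0


def test_candidates_exclude_other_known_associations():
    enh, dis, assoc = _small_world()
    res = loocv(
        "rwdisenh",
        enhancer_network=enh,
        disease_network=dis,
        associations=assoc,
        view="enhancer",
    )
    rec = next(r for r in res.records if r.entity == "D1")
    # 4 enhancers, 2 known to D1: candidates = the other 2 enhancers
    assert rec.n_candidates == 2


def test_enhancer_centric_view_runs():
    enh = WeightedNetwork.from_edges(("e1", "e2"), [("e1", "e2", 1.0)])
    dis = WeightedNetwork.from_edges(
        ("D1", "D2", "D3"), [("D1", "D2", 0.5), ("D2", "D3", 0.5)]
    )
    assoc = AssociationTable((("D1", "e1"), ("D2", "e1"), ("D3", "e2")))
    res = loocv(
        "rwdisenh",
        enhancer_network=enh,
        disease_network=dis,
        associations=assoc,
        view="disease",
    )
    assert {r.entity for r in res.records} == {"e1"}
    assert "e2" in res.skipped


def test_all_methods_produce_valid_records():
    enh, dis, assoc = _small_world()
    for method in ("rwdisenh", "prp", "maxlink"):
        for view in ("hetero", "enhancer"):
            res = loocv(
                method,
                enhancer_network=enh,
                disease_network=dis,
                associations=assoc,
                view=view,
            )
            assert res.records
            for r in res.records:
                assert 1 <= r.rank <= r.n_candidates + 1


def test_loocv_input_validation():
    enh, dis, assoc = _small_world()
    with pytest.raises(ValueError):
        loocv("nope", enhancer_network=enh, disease_network=dis, associations=assoc)
    with pytest.raises(ValueError):
        loocv(
            "rwdisenh",
            enhancer_network=enh,
            disease_network=dis,
            associations=assoc,
            view="sideways",
        )
    with pytest.raises(ValueError):
        loocv(
            "rwdisenh",
            enhancer_network=enh,
            disease_network=dis,
            associations=assoc,
            params={"bogus": 1.0},
        )


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def test_sweep_default_grid_is_fifteen_rows():
    calls = []

    def evaluate(params):
        calls.append(dict(params))
        return {"d1": 0.8, "d2": 0.9}

    table = parameter_sweep(evaluate)
    assert len(table) == 15
    assert set(table["parameter"]) == {"gamma", "eta", "lambda"}
    assert sorted(set(table["value"])) == [0.1, 0.3, 0.5, 0.7, 0.9]
    # off-axis parameters stay at the baseline
    for c in calls:
        assert sum(v != 0.5 for v in c.values()) <= 1


def test_sweep_degenerate_single_point():
    table = parameter_sweep(
        lambda params: {"d": 0.7}, parameters=("gamma",), values=(0.5,)
    )
    assert len(table) == 1 and table.loc[0, "mean_auc"] == 0.7


def test_sweep_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        parameter_sweep(lambda p: {"d": 0.5}, values=(0.0, 0.5))
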