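import numpy as np
import pandas as pd
import pytest

from edsurrogate import (
    CostTable,
    ResourceConfig,
    build_grid,
    cost_benefit,
    escalate_coefficients,
    grid_configs,
    scenario_cost,
)

# the published coefficient matrix, frozen for comparison
PUBLISHED = {
    "d0.0": {"pn": 1.00, "nn": 0.80, "cn": 0.60, "bn": 0.50, "tn": 0.40},
    "d0.1": {"pn": 1.20, "nn": 0.96, "cn": 0.72, "bn": 0.60, "tn": 0.48},
    "d0.2": {"pn": 1.56, "nn": 1.25, "cn": 0.94, "bn": 0.78, "tn": 0.62},
    "d0.3": {"pn": 2.34, "nn": 1.87, "cn": 1.40, "bn": 1.17, "tn": 0.94},
}


@pytest.fixture(scope="module")
def table():
    return escalate_coefficients()


def test_escalated_matrix_reproduces_published_cells(table):
    rounded = table.rounded()
    for level, row in PUBLISHED.items():
        for resource, value in row.items():
            assert rounded.loc[level, resource] == pytest.approx(value)


def test_column_sums_and_multipliers(table):
    sums = table.column_sums()
    for resource, total in {"pn": 6.10, "nn": 4.88, "cn": 3.66,
                            "bn": 3.05, "tn": 2.44}.items():
        assert sums[resource] == pytest.approx(total)
    assert table.multipliers == (1.0, 1.2, 1.3, 1.5)
    assert sum(table.multipliers) == pytest.approx(5.00)


def test_zero_escalation_keeps_base_rows():
    t = escalate_coefficients(escalations=(0.0, 0.0))
    r = t.rounded()
    assert (r.iloc[0] == r.iloc[1]).all() and (r.iloc[0] == r.iloc[2]).all()


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        escalate_coefficients(escalations=(-0.1,))
    with pytest.raises(ValueError):
        escalate_coefficients(base={"pn": 0.0})


def test_table_csv_roundtrip(tmp_path, table):
    p = tmp_path / "table.csv"
    table.to_csv(p)
    back = CostTable.from_csv(p)
    pd.testing.assert_frame_equal(back.rounded(), table.rounded())
    assert back.multipliers == table.multipliers


def test_scenario_cost_base_config(table):
    cfg = ResourceConfig(1, 1, 1, 1, 1)
    assert scenario_cost(cfg, table, "d0.0") == pytest.approx(3.30)


def test_scenario_cost_reference_staffing_highest_level(table):
    cfg = ResourceConfig(3, 3, 2, 5, 2)
    # brute-force oracle: direct count-weighted sum over the printed row
    expected = sum(
        n * PUBLISHED["d0.3"][r]
        for r, n in zip(("pn", "nn", "cn", "bn", "tn"), (3, 3, 2, 5, 2))
    )
    assert expected == pytest.approx(23.16)
    assert scenario_cost(cfg, table, "d0.3") == pytest.approx(expected)


def test_scenario_cost_linear_in_each_count(table):
    base = ResourceConfig(1, 1, 1, 1, 1)
    c0 = scenario_cost(base, table, "d0.2")
    for f in ("pn", "nn", "cn", "bn", "tn"):
        bumped = dict(base.as_dict())
        bumped[f] += 2
        delta = scenario_cost(bumped, table, "d0.2") - c0
        assert delta == pytest.approx(2 * table.coefficient(f, "d0.2"))


def test_scenario_cost_unknown_resource_rejected(table):
    with pytest.raises(KeyError):
        scenario_cost({"pn": 1, "robot": 2}, table, "d0.0")
    with pytest.raises(KeyError):
        scenario_cost(ResourceConfig(), table, "d9.9")


def test_costs_increase_with_level(table):
    for cfg in grid_configs()[:10]:
        costs = [scenario_cost(cfg, table, lv) for lv in table.levels]
        assert all(a < b for a, b in zip(costs, costs[1:]))


def test_grid_default_is_balanced_216():
    g = build_grid()
    assert len(g) == 216
    assert g["scenario"].nunique() == 108
    assert g["pn"].mean() == pytest.approx(2.000)
    for col, levels in {"pn": 3, "nn": 3, "cn": 2, "bn": 3, "tn": 2}.items():
        counts = g[col].value_counts()
        assert len(counts) == levels
        assert counts.nunique() == 1  # balanced


def test_grid_lexicographic_and_degenerate():
    g = build_grid(replicates=1)
    assert list(g.iloc[0][["pn", "nn", "cn", "bn", "tn"]]) == [1, 1, 1, 1, 1]
    assert list(g.iloc[-1][["pn", "nn", "cn", "bn", "tn"]]) == [3, 3, 2, 3, 2]
    single = build_grid({f: (1,) for f in ("pn", "nn", "cn", "bn", "tn")}, 1)
    assert len(single) == 1
    with pytest.raises(ValueError):
        build_grid({"pn": ()}, 1)


def test_cost_benefit_zero_waits(table):
    daily = pd.DataFrame({"pnt": [10, 12], "wt": [0.0, 0.0]})
    sc = cost_benefit(daily, ResourceConfig(1, 1, 1, 1, 1), table, "d0.0")
    assert sc.cost_wt == pytest.approx(0.0)


def test_cost_benefit_hand_example(table):
    daily = pd.DataFrame({"pnt": [10], "wt": [0.5]})
    sc = cost_benefit(daily, ResourceConfig(1, 1, 1, 1, 1), table, "d0.0",
                      revenue_per_patient=5.0)
    assert sc.cost_pnt == pytest.approx(10 * 3.30)
    assert sc.cost_wt == pytest.approx(0.5 / 10 * 3.30)
    assert sc.net == pytest.approx(5.0 * 10 - sc.cost_pnt - sc.cost_wt)


def test_cost_benefit_net_monotone_in_level(table):
    daily = pd.DataFrame({"pnt": [8, 9, 10], "wt": [0.4, 0.5, 0.6]})
    nets = [
        cost_benefit(daily, ResourceConfig(2, 2, 1, 2, 1), table, lv,
                     revenue_per_patient=3.0).net
        for lv in table.levels
    ]
    assert all(a > b for a, b in zip(nets, nets[1:]))


def test_cost_benefit_zero_throughput_flagged(table):
    daily = pd.DataFrame({"pnt": [0], "wt": [np.nan]})
    sc = cost_benefit(daily, ResourceConfig(1, 1, 1, 1, 1), table, "d0.1")
    assert not sc.wt_defined
    assert sc.cost_wt is None and sc.net is None and sc.breakeven is None
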