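import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from streamstate import (
    OccurrencePanel,
    assign_group,
    credible_interval,
    group_hypotheses,
    load_trait_table,
    read_occurrence_table,
    write_occurrence_table,
)
from streamstate.panel import CredibleSummary, DuplicateKeyError, SchemaError


@pytest.fixture(scope="module")
def trait_table():
    return load_trait_table()


class TestOccurrenceIO:
    def _write(self, tmp_path, rows, header="genus,stream,frequency,battery,occasion,occurrence"):
        path = tmp_path / "occ.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return str(path)

    def test_small_table_counts(self, tmp_path):
        path = self._write(
            tmp_path,
            ["Baetidae,1,C,1,1,0", "Baetidae,1,C,1,2,1", "Baetidae,1,C,1,3,1"],
        )
        panel = read_occurrence_table(path)
        assert panel.occurrences.sum() == 2
        assert panel.n_genera == 1 and panel.n_series == 1 and panel.n_occasions == 3

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write(tmp_path, ["Baetidae,1,C,1,0"], header="genus,stream,frequency,battery,occurrence")
        with pytest.raises(SchemaError):
            read_occurrence_table(path)

    def test_non_binary_occurrence_rejected(self, tmp_path):
        path = self._write(tmp_path, ["Baetidae,1,C,1,1,2"])
        with pytest.raises(ValueError):
            read_occurrence_table(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = self._write(tmp_path, ["Baetidae,1,C,1,1,0", "Baetidae,1,C,1,1,1"])
        with pytest.raises(DuplicateKeyError):
            read_occurrence_table(path)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        occ = rng.integers(0, 2, size=(3, 4, 5)).astype(np.int8)
        meta = pd.DataFrame(
            {
                "stream": [1, 1, 2, 2],
                "frequency": ["C", "F1", "C", "F2"],
                "battery": [1, 1, 2, 2],
            }
        )
        panel = OccurrencePanel(
            occ,
            ["Baetidae", "Chironomidae", "Simuliidae"],
            meta,
            [23, 27, 31, 35, 39],
            {"Baetidae": 6, "Chironomidae": 3, "Simuliidae": 5},
        )
        path = str(tmp_path / "rt.csv")
        write_occurrence_table(panel, path)
        back = read_occurrence_table(path, occasion_days=[23, 27, 31, 35, 39])
        assert back.genera == sorted(panel.genera)
        # align genus order before comparing tensors
        order = [panel.genera.index(g) for g in back.genera]
        s_order = np.lexsort(
            (meta["battery"].to_numpy(), meta["frequency"].to_numpy(), meta["stream"].to_numpy())
        )
        assert np.array_equal(back.occurrences, occ[order][:, s_order, :])
        assert np.array_equal(back.occasion_days, panel.occasion_days)

    def test_all_zero_genus_is_kept_but_flagged(self, tmp_path):
        rows = [f"Baetidae,1,C,1,{t},0" for t in range(1, 4)]
        rows += [f"Chironomidae,1,C,1,{t},1" for t in range(1, 4)]
        path = self._write(tmp_path, rows)
        with pytest.warns(UserWarning, match="Baetidae"):
            panel = read_occurrence_table(path)
        assert panel.all_zero_genera() == ["Baetidae"]
        assert "Baetidae" in panel.genera


class TestPanelInvariants:
    def test_values_must_be_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            OccurrencePanel(
                np.full((1, 1, 2), 2),
                ["g"],
                pd.DataFrame({"stream": [1], "frequency": ["C"], "battery": [1]}),
                [1, 2],
                {"g": 1},
            )

    def test_days_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            OccurrencePanel(
                np.zeros((1, 1, 2), dtype=int),
                ["g"],
                pd.DataFrame({"stream": [1], "frequency": ["C"], "battery": [1]}),
                [5, 5],
                {"g": 1},
            )

    def test_every_genus_needs_a_group(self):
        with pytest.raises(ValueError, match="without a group"):
            OccurrencePanel(
                np.zeros((1, 1, 2), dtype=int),
                ["g"],
                pd.DataFrame({"stream": [1], "frequency": ["C"], "battery": [1]}),
                [1, 2],
                {},
            )


class TestTraitGroups:
    @pytest.mark.parametrize(
        "taxon,expected",
        [("Chironomidae", 3), ("Simuliidae", 5), ("Baetidae", 6), ("Macrelmis", 1), ("Oecetis", 9)],
    )
    def test_known_taxa(self, trait_table, taxon, expected):
        assert assign_group(trait_table, taxon) == expected

    def test_unknown_taxon(self, trait_table):
        with pytest.raises(KeyError):
            assign_group(trait_table, "NotAGenus")

    def test_all_nine_groups_represented(self, trait_table):
        assert {rec.group for rec in trait_table} == set(range(1, 10))

    def test_hypothesis_levels_consistent_within_groups(self, trait_table):
        levels = group_hypotheses(trait_table)
        assert set(levels) == set(range(1, 10))
        assert levels[3] == ("low", "high")
        assert levels[8] == ("very high", "low")


class TestCredibleInterval:
    def test_interpolated_quantiles(self):
        ci = credible_interval(np.arange(1, 101), level=0.5)
        assert ci.median == pytest.approx(50.5)
        assert ci.lower == pytest.approx(25.75)
        assert ci.upper == pytest.approx(75.25)

    def test_degenerate_draws(self):
        ci = credible_interval([0.3] * 10, level=0.9)
        for value in (ci.lower, ci.upper, ci.mean):
            assert value == pytest.approx(0.3)

    def test_two_point_interpolation(self):
        ci = credible_interval([0.0, 1.0], level=0.95)
        assert ci.lower == pytest.approx(0.025)
        assert ci.upper == pytest.approx(0.975)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            credible_interval([0.5])

    @settings(deadline=None, max_examples=25)
    @given(
        draws=hst.lists(hst.floats(0, 1, allow_nan=False), min_size=3, max_size=40),
    )
    def test_level_near_one_approaches_range(self, draws):
        ci = credible_interval(draws, level=1 - 1e-9)
        assert ci.lower == pytest.approx(min(draws), abs=1e-6)
        assert ci.upper == pytest.approx(max(draws), abs=1e-6)

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError):
            CredibleSummary(mean=0.5, median=0.5, lower=0.8, upper=0.2)
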