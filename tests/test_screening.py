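"""Key-target and important-pathway screening cascades; cross-talk fixture."""

import random

import pandas as pd
import pytest

from netpharm.build import build_ctn
from netpharm.centrality import centrality_table
from netpharm.model import InteractionEdge
from netpharm.screening import (
    CrosstalkEdge,
    DEFAULT_NONSPECIFIC_BLOCKLIST,
    HUB_PATHWAY,
    PathwayCriteria,
    TargetCriteria,
    load_crosstalk,
    screen_important_pathways,
    screen_key_targets,
    validate_crosstalk,
)


def target_table(rows):
    """Centrality table from {node: (class, degree, betweenness, closeness)}."""
    return pd.DataFrame(
        {
            "node_class": [v[0] for v in rows.values()],
            "degree": [v[1] for v in rows.values()],
            "betweenness": [v[2] for v in rows.values()],
            "betweenness_norm": [v[2] for v in rows.values()],
            "closeness": [v[3] for v in rows.values()],
        },
        index=pd.Index(rows.keys(), name="node"),
    )


class TestKeyTargets:
    def test_single_target_fails_strict_mean_comparison(self):
        # the mean of one element is itself, so strict > excludes it
        table = target_table({"t1": ("target", 3, 1.0, 0.5), "c1": ("compound", 3, 0.0, 0.4)})
        result = screen_key_targets(table, TargetCriteria(top_k_degree=10))
        assert result.selected == ()
        assert result.audit["t1"]["in_top_k"] is True

    def test_toy_cascade(self):
        table = target_table(
            {
                "hub": ("target", 5, 4.0, 0.9),
                "mid": ("target", 4, 3.5, 0.2),
                "low1": ("target", 1, 0.0, 0.3),
                "low2": ("target", 1, 0.0, 0.3),
                "c": ("compound", 9, 0.0, 0.5),
            }
        )
        result = screen_key_targets(table, TargetCriteria(top_k_degree=2))
        # both high-degree targets are candidates; only hub beats both means
        assert result.audit["hub"]["in_top_k"] and result.audit["mid"]["in_top_k"]
        assert not result.audit["low1"]["in_top_k"]
        assert result.selected == ("hub",)
        assert result.audit["mid"]["closeness_above_mean"] is False

    def test_boundary_ties_all_included(self):
        rows = {f"t{i}": ("target", 5, 2.0, 0.9) for i in range(4)}
        rows.update({f"u{i}": ("target", 1, 0.0, 0.1) for i in range(4)})
        table = target_table(rows)
        result = screen_key_targets(table, TargetCriteria(top_k_degree=2))
        # all four degree-5 targets tie at the k-th boundary value
        assert set(result.selected) == {f"t{i}" for i in range(4)}

    def test_selection_independent_of_row_order(self):
        rng = random.Random(13)
        rows = {
            f"t{i:02d}": ("target", rng.randint(1, 6), rng.random() * 3, rng.random())
            for i in range(20)
        }
        base = screen_key_targets(target_table(rows), TargetCriteria(top_k_degree=5))
        for _ in range(5):
            items = list(rows.items())
            rng.shuffle(items)
            permuted = screen_key_targets(
                target_table(dict(items)), TargetCriteria(top_k_degree=5)
            )
            assert permuted.selected == base.selected

    def test_enlarging_top_k_never_removes_targets(self):
        rng = random.Random(29)
        rows = {
            f"t{i:02d}": ("target", rng.randint(1, 9), rng.random() * 3, rng.random())
            for i in range(25)
        }
        table = target_table(rows)
        previous: set = set()
        for k in range(1, 12):
            selected = set(screen_key_targets(table, TargetCriteria(top_k_degree=k)).selected)
            assert previous <= selected
            previous = selected

    def test_empty_target_class_is_hard_error(self):
        table = target_table({"c": ("compound", 1, 0.0, 0.5)})
        with pytest.raises(ValueError, match="target"):
            screen_key_targets(table)

    def test_deterministic_ordering(self):
        table = target_table(
            {
                "b": ("target", 5, 2.0, 0.9),
                "a": ("target", 5, 2.0, 0.9),
                "z": ("target", 6, 1.5, 0.9),
                "w": ("target", 1, 0.0, 0.0),
            }
        )
        result = screen_key_targets(table, TargetCriteria(top_k_degree=3))
        assert result.selected == ("z", "a", "b")


class TestImportantPathways:
    @staticmethod
    def planted_table():
        """12 high-degree pathways: 4 blocklisted, 2 with low closeness, 6 clean."""
        rows = {}
        blocked = sorted(DEFAULT_NONSPECIFIC_BLOCKLIST)
        for i, name in enumerate(blocked):
            rows[name] = ("pathway", 12, 8.0, 0.9)
        for i in range(2):
            rows[f"lowclose{i}"] = ("pathway", 12, 8.0, 0.05)
        for i in range(6):
            rows[f"clean{i}"] = ("pathway", 12, 8.0, 0.9)
        # background: many small pathways
        for i in range(30):
            rows[f"bg{i:02d}"] = ("pathway", 2, 0.1, 0.3)
        rows["t"] = ("target", 40, 0.0, 0.5)
        return target_table(rows)

    def test_twelve_planted_six_survive(self):
        result = screen_important_pathways(self.planted_table(), PathwayCriteria())
        assert set(result.selected) == {f"clean{i}" for i in range(6)}
        for name in DEFAULT_NONSPECIFIC_BLOCKLIST:
            assert result.audit[name]["removed_at"] == "nonspecific"
        for i in range(2):
            assert result.audit[f"lowclose{i}"]["removed_at"] == "closeness"

    def test_degree_exactly_at_cutoff_rejected(self):
        table = target_table(
            {
                "edge6": ("pathway", 6, 9.0, 0.9),
                "deg7": ("pathway", 7, 9.0, 0.9),
                "bg": ("pathway", 1, 0.0, 0.1),
                "t": ("target", 10, 0.0, 0.5),
            }
        )
        result = screen_important_pathways(table, PathwayCriteria(min_degree_exclusive=6))
        assert result.audit["edge6"]["removed_at"] == "degree"
        assert result.selected == ("deg7",)

    def test_blocklist_matches_display_names(self):
        table = target_table(
            {
                "hsa01100": ("pathway", 12, 9.0, 0.9),
                "hsa04020": ("pathway", 12, 9.0, 0.9),
                "bg": ("pathway", 1, 0.0, 0.1),
                "t": ("target", 10, 0.0, 0.5),
            }
        )
        result = screen_important_pathways(
            table,
            PathwayCriteria(),
            pathway_names={"hsa01100": "Metabolic pathways",
                           "hsa04020": "Calcium signaling pathway"},
        )
        assert result.audit["hsa01100"]["removed_at"] == "nonspecific"
        assert result.selected == ("hsa04020",)

    def test_raising_degree_cutoff_never_adds_pathways(self):
        table = self.planted_table()
        previous = None
        for cutoff in range(0, 15):
            selected = set(
                screen_important_pathways(
                    table, PathwayCriteria(min_degree_exclusive=cutoff)
                ).selected
            )
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_empty_pathway_class_is_hard_error(self):
        table = target_table({"t": ("target", 1, 0.0, 0.5)})
        with pytest.raises(ValueError, match="pathway"):
            screen_important_pathways(table)


class TestCrosstalk:
    def test_fixture_loads_and_validates(self, crosstalk_path):
        edges = load_crosstalk(crosstalk_path)
        assert len(edges) >= 7
        validate_crosstalk(edges)
        feedback = [e for e in edges if e.is_feedback]
        assert feedback, "curated map must mark feedback regulations"

    def test_every_pathway_feeds_the_hub(self, crosstalk_path):
        edges = load_crosstalk(crosstalk_path)
        sources_into_hub = {e.from_pathway for e in edges if e.to_pathway == HUB_PATHWAY}
        others = {e.from_pathway for e in edges} | {e.to_pathway for e in edges}
        assert others - {HUB_PATHWAY} == sources_into_hub

    def test_unknown_pathway_name_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "from_pathway,to_pathway,connector,is_feedback\n"
            "estrogen signalling pathway,NF-κB signaling pathway,x,0\n",
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match="unknown pathway"):
            load_crosstalk(p)

    def test_self_crosstalk_rejected(self):
        with pytest.raises(ValueError, match="self"):
            CrosstalkEdge("MAPK signaling pathway", "MAPK signaling pathway")

    def test_empty_fixture_fails_validation_loudly(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("from_pathway,to_pathway,connector,is_feedback\n", encoding="utf-8")
        edges = load_crosstalk(p)
        assert edges == []
        with pytest.raises(ValueError, match="no edge into"):
            validate_crosstalk(edges)
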