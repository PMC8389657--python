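"""Screen, six-group classification, top-k selection and qPCR re-ranking."""

import itertools

import pytest

from mdscreen import (
    GROUP_ORDER,
    GroupLabel,
    assign_group,
    classify,
    rerank_with_qpcr,
    score_pair,
    screen_by_fold,
    select_top_k,
)


def _score(gene, dmo, dgr, group=None):
    s = score_pair(gene, dmo, dgr)
    s.group = group
    return s


# -- fold screen -----------------------------------------------------------

def test_screen_is_strict_and_two_sided():
    scores = [
        _score("at_threshold", 1.25, 1.25),   # fold = 2.5 exactly -> excluded
        _score("up", 1.3, 1.3),               # fold = 2.6
        _score("down", -1.3, -1.3),           # fold = -2.6
        _score("weak", 1.2, 1.2),             # fold = 2.4
        _score("flat", 0.0, 0.0),
    ]
    kept = screen_by_fold(scores, 2.5)
    assert [s.gene_id for s in kept] == ["up", "down"]


def test_screen_monotone_in_threshold():
    scores = [_score(f"g{k}", d, d) for k, d in enumerate([0.1, 0.5, 1.0, 1.3, 1.5, 2.0, 3.0])]
    sizes = [len(screen_by_fold(scores, t)) for t in (0.5, 1.0, 2.5, 4.0, 7.0)]
    assert sizes == sorted(sizes, reverse=True)


def test_screen_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        screen_by_fold([], 0.0)


# -- group assignment ------------------------------------------------------

@pytest.mark.parametrize(
    "dmo, dgr, expected",
    [
        (2.0, 0.5, GroupLabel.MO_UP),     # F=2.5, IF=3.75
        (-2.0, -1.0, GroupLabel.MO_DOWN), # F=-3, IF=3 (Mo-dominant, down)
        (0.5, 2.0, GroupLabel.GR_UP),     # F=2.5, IF=-3.75
        (-1.0, -2.0, GroupLabel.GR_DOWN),
        (1.3, 1.3, GroupLabel.UP),        # IF=0
        (-1.3, -1.3, GroupLabel.DOWN),
    ],
)
def test_assign_group_examples(dmo, dgr, expected):
    assert assign_group(score_pair("g", dmo, dgr)) == expected


def test_assign_group_boundary_goes_to_central_band():
    """|IF| exactly at the threshold stays in Up/Down (strict flanking rule)."""
    s = score_pair("g", 0, 0)
    s.fold, s.influence_factor = 3.0, 1.0
    assert assign_group(s) == GroupLabel.UP
    s.influence_factor = -1.0
    assert assign_group(s) == GroupLabel.UP
    s.fold = -3.0
    assert assign_group(s) == GroupLabel.DOWN


def test_assign_group_zero_fold_raises():
    with pytest.raises(ValueError, match="fold is 0"):
        assign_group(_score("g", 1.0, -1.0))


def test_partition_exhaustive_over_sign_and_band():
    """Every (sign F) x (IF band) combination maps to exactly one label."""
    seen = set()
    for fold in (2.6, -2.6):
        for influence in (-5.0, -1.0, 0.0, 1.0, 5.0):
            s = _score("g", 0.0, 0.1)
            s.fold, s.influence_factor = fold, influence
            label = assign_group(s)
            assert isinstance(label, GroupLabel)
            seen.add((fold > 0, label))
    # 2 fold signs x 3 effective bands = 6 distinct labels
    assert {label for _, label in seen} == set(GroupLabel)


def test_subset_swap_duality():
    """Swapping Mo and Gr swaps Mo-* with Gr-* and fixes Up/Down."""
    swap = {
        GroupLabel.MO_UP: GroupLabel.GR_UP,
        GroupLabel.MO_DOWN: GroupLabel.GR_DOWN,
        GroupLabel.GR_UP: GroupLabel.MO_UP,
        GroupLabel.GR_DOWN: GroupLabel.MO_DOWN,
        GroupLabel.UP: GroupLabel.UP,
        GroupLabel.DOWN: GroupLabel.DOWN,
    }
    cases = [(2.0, 0.5), (-2.0, -1.0), (0.5, 2.0), (-1.0, -2.0), (1.3, 1.3), (-1.4, -1.3)]
    for dmo, dgr in cases:
        direct = assign_group(score_pair("g", dmo, dgr))
        swapped = assign_group(score_pair("g", dgr, dmo))
        assert swapped == swap[direct]


# -- top-k selection -------------------------------------------------------

def _populated_groups(per_group=4):
    """per_group genes in each of the six groups, distances spread out."""
    recipes = {
        GroupLabel.UP: (1.0, 1.0),
        GroupLabel.DOWN: (-1.0, -1.0),
        GroupLabel.MO_UP: (1.0, 0.2),
        GroupLabel.MO_DOWN: (-1.0, -0.2),
        GroupLabel.GR_UP: (0.2, 1.0),
        GroupLabel.GR_DOWN: (-0.2, -1.0),
    }
    scores = []
    for gi, (group, (a, b)) in enumerate(recipes.items()):
        for k in range(per_group):
            scale = 2.5 + 0.2 * k  # larger k -> larger |fold| -> larger distance
            scores.append(_score(f"{group.value}_{k}", a * scale, b * scale))
    return classify(screen_by_fold(scores, 2.5))


def test_select_top_k_cardinality_full_groups():
    screened = _populated_groups(per_group=4)
    result = select_top_k(screened, k=3)
    assert len(result.selected) == 18
    assert [g.value for g in GROUP_ORDER] == ["Up", "Down", "Gr-Up", "Gr-Down", "Mo-Up", "Mo-Down"]
    # selected genes appear once each, in group order
    assert len({s.gene_id for s in result.selected}) == 18
    groups_in_order = [s.group for s in result.selected]
    assert groups_in_order == [g for g in GROUP_ORDER for _ in range(3)]


def test_select_top_k_takes_largest_distance():
    screened = _populated_groups(per_group=5)
    result = select_top_k(screened, k=3)
    for group in GROUP_ORDER:
        members = [s for s in screened if s.group == group]
        best = sorted(members, key=lambda s: -s.distance)[:3]
        assert {s.gene_id for s in result.groups[group][:3]} == {s.gene_id for s in best}


def test_select_top_k_empty_group():
    screened = [s for s in _populated_groups(4) if s.group != GroupLabel.GR_UP]
    result = select_top_k(screened, k=3)
    assert len(result.selected) == 15
    assert result.groups[GroupLabel.GR_UP] == []


def test_select_top_k_tie_broken_by_gene_id():
    a = _score("zzz", 2.0, 0.5)
    b = _score("aaa", 2.0, 0.5)   # identical scores -> tie on distance
    c = _score("mmm", 3.0, 0.5)
    screened = classify([a, b, c])
    for perm in itertools.permutations(screened):
        result = select_top_k(list(perm), k=2)
        assert [s.gene_id for s in result.groups[GroupLabel.MO_UP][:2]] == ["mmm", "aaa"]


def test_select_top_k_order_invariant():
    screened = _populated_groups(per_group=5)
    baseline = [s.gene_id for s in select_top_k(screened, k=3).selected]
    assert [s.gene_id for s in select_top_k(screened[::-1], k=3).selected] == baseline


def test_select_top_k_requires_groups_and_valid_k():
    with pytest.raises(ValueError, match="k must be"):
        select_top_k([], k=0)
    with pytest.raises(ValueError, match="no group label"):
        select_top_k([_score("g", 2.0, 1.0)], k=1)


# -- qPCR re-ranking -------------------------------------------------------

def test_rerank_idempotent_when_qpcr_equals_microarray():
    screened = _populated_groups(4)
    result = select_top_k(screened, k=3)
    deltas = {s.gene_id: (s.delta_mo, s.delta_gr) for s in result.selected}
    reranked = rerank_with_qpcr(result, deltas)
    expected = sorted(result.selected, key=lambda s: (-s.distance, s.gene_id))
    assert [s.gene_id for s in reranked.final_ranking] == [s.gene_id for s in expected]
    assert reranked.final_target == expected[0].gene_id


def test_rerank_single_covered_gene_is_target():
    result = select_top_k(_populated_groups(4), k=3)
    gene = result.selected[5].gene_id
    reranked = rerank_with_qpcr(result, {gene: (0.1, 0.1)})
    assert reranked.final_target == gene
    assert reranked.final_ranking[0].gene_id == gene
    # uncovered genes trail the ranking and keep their count
    assert len(reranked.final_ranking) == len(result.selected)


def test_rerank_prefers_larger_recalculated_distance():
    result = select_top_k(_populated_groups(4), k=3)
    g1, g2 = result.selected[0].gene_id, result.selected[1].gene_id
    # (2, 0.5): D ~ 4.507; (1, 1): D = 2
    reranked = rerank_with_qpcr(result, {g1: (1.0, 1.0), g2: (2.0, 0.5)})
    assert reranked.final_target == g2
    assert reranked.qpcr_scores[g2].distance == pytest.approx(4.506939094329987, rel=1e-12)


def test_rerank_requires_coverage():
    result = select_top_k(_populated_groups(4), k=3)
    with pytest.raises(ValueError, match="coverage"):
        rerank_with_qpcr(result, {"not_selected": (1.0, 1.0)})


def test_selection_frame_columns():
    result = select_top_k(_populated_groups(4), k=2)
    frame = result.to_frame()
    assert list(frame.columns) == [
        "gene_id", "group", "rank_in_group", "distance", "distance_qpcr", "is_final_target",
    ]
    assert len(frame) == 12
    assert frame["distance_qpcr"].isna().all()
    assert not frame["is_final_target"].any()
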