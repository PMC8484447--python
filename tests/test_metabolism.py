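import numpy as np
import pandas as pd
import pytest

from holoeve.metabolism import (
    capability_shares,
    category_expression,
    classify_reactions,
    compute_qmf,
    filter_expressed,
)

SAMPLES = ["ambient_r1", "ambient_r2", "heat_r1", "heat_r2"]


def _ann(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "member", "ko",
                                       "pathway", "ec"])


class TestFilterExpressed:
    def test_two_qualifying_samples_kept(self):
        tpm = pd.DataFrame([[12, 3, 3, 11]], index=["t1"], columns=SAMPLES)
        assert filter_expressed(tpm) == ["t1"]

    def test_single_qualifying_sample_dropped(self):
        tpm = pd.DataFrame([[9.99, 50, 0, 0]], index=["t1"], columns=SAMPLES)
        assert filter_expressed(tpm) == []

    def test_conditions_pooled_across_treatment(self):
        # qualifies only by combining one ambient and one heat sample
        tpm = pd.DataFrame([[15, 0, 15, 0]], index=["t1"], columns=SAMPLES)
        assert filter_expressed(tpm) == ["t1"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        tpm = pd.DataFrame(
            rng.exponential(8, size=(50, 4)),
            index=[f"t{i}" for i in range(50)], columns=SAMPLES,
        )
        kept = filter_expressed(tpm, min_tpm=10, min_samples=2)
        expected = [
            t for t in tpm.index
            if int((tpm.loc[t] >= 10).sum()) >= 2
        ]
        assert kept == expected

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(
            rng.exponential(8, size=(40, 4)),
            index=[f"t{i}" for i in range(40)], columns=SAMPLES,
        )
        base = set(filter_expressed(tpm, 10, 2))
        assert set(filter_expressed(tpm, 20, 2)) <= base
        assert set(filter_expressed(tpm, 10, 3)) <= base

    def test_unlabelled_columns_rejected(self):
        tpm = pd.DataFrame([[1, 2]], index=["t1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="condition"):
            filter_expressed(tpm)


class TestComputeQmf:
    def test_two_pathway_proportions(self):
        ann = _ann([("t1", "host", "K1", "P1", ""),
                    ("t2", "host", "K2", "P2", "")])
        tpm = pd.DataFrame([[300.0] * 4, [700.0] * 4],
                           index=["t1", "t2"], columns=SAMPLES)
        res = compute_qmf(tpm, ann, min_tpm=0, min_samples=0)
        prop = res.proportions.set_index(["pathway", "condition"])["value"]
        assert prop[("P1", "ambient")] == pytest.approx(0.3)
        assert prop[("P2", "heat")] == pytest.approx(0.7)

    def test_identical_conditions_give_unit_fold_change(self):
        rng = np.random.default_rng(2)
        ann = _ann([(f"t{i}", "host", "K", f"P{i % 3}", "")
                    for i in range(9)])
        vals = rng.uniform(20, 100, size=(9, 1))
        tpm = pd.DataFrame(np.repeat(vals, 4, axis=1),
                           index=[f"t{i}" for i in range(9)], columns=SAMPLES)
        res = compute_qmf(tpm, ann)
        assert (res.fold_change["fold_change"] == 1.0).all()
        assert (res.fold_change["log2_fold_change"] == 0.0).all()

    def test_proportions_sum_to_one_per_member_condition(self):
        rng = np.random.default_rng(3)
        members = ["host", "symbiont", "bacteria"]
        ann = _ann([
            (f"t{i}", members[i % 3], "K",
             ";".join(rng.choice([f"P{j}" for j in range(5)],
                                 size=rng.integers(1, 3), replace=False)), "")
            for i in range(60)
        ])
        tpm = pd.DataFrame(rng.exponential(50, size=(60, 4)),
                           index=[f"t{i}" for i in range(60)],
                           columns=SAMPLES)
        res = compute_qmf(tpm, ann, min_tpm=0, min_samples=0)
        sums = res.proportions.groupby(["member", "condition"])["value"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_library_total_mode_bounded_by_one(self):
        ann = _ann([("t1", "host", "K", "P1", ""),
                    ("t2", "symbiont", "K", "P1", "")])
        tpm = pd.DataFrame([[100.0] * 4, [200.0] * 4],
                           index=["t1", "t2", ], columns=SAMPLES)
        res = compute_qmf(tpm, ann, denominator="library_total",
                          min_tpm=0, min_samples=0)
        total = res.proportions.groupby("condition")["value"].sum()
        assert (total <= 1.0 + 1e-12).all()

    def test_matches_brute_force_group_and_normalise(self):
        rng = np.random.default_rng(4)
        members = ["host", "symbiont", "bacteria"]
        paths = [f"P{j}" for j in range(5)]
        ann_rows = []
        for i in range(30):
            pw = rng.choice(paths, size=rng.integers(1, 3), replace=False)
            ann_rows.append((f"t{i}", members[i % 3], "K",
                             ";".join(sorted(pw)), ""))
        ann = _ann(ann_rows)
        tpm = pd.DataFrame(rng.exponential(40, size=(30, 4)),
                           index=[f"t{i}" for i in range(30)],
                           columns=SAMPLES)
        kept = filter_expressed(tpm, 10, 2)
        res = compute_qmf(tpm, ann, kept=kept)
        means = {
            t: {"ambient": tpm.loc[t, SAMPLES[:2]].mean(),
                "heat": tpm.loc[t, SAMPLES[2:]].mean()}
            for t in tpm.index
        }
        lookup = res.proportions.set_index(
            ["member", "pathway", "condition"])["value"]
        for (m, p, c), got in lookup.items():
            num = sum(
                means[t][c] for t, mem, _, pws, _ in ann.itertuples(index=False)
                if mem == m and t in kept and p in pws.split(";")
            )
            den = sum(
                means[t][c]
                for t, mem, _, pws, _ in ann.itertuples(index=False)
                for _pw in pws.split(";")
                if mem == m and t in kept and _pw
            )
            assert got == pytest.approx(num / den, abs=1e-12)

    def test_infinite_fold_change_flagged(self):
        ann = _ann([("t1", "host", "K", "P1", ""),
                    ("t2", "host", "K", "P2", "")])
        tpm = pd.DataFrame([[50, 50, 50, 50], [0, 0, 40, 40]],
                           index=["t1", "t2"], columns=SAMPLES, dtype=float)
        res = compute_qmf(tpm, ann, min_tpm=0, min_samples=0)
        row = res.fold_change.set_index("pathway").loc["P2"]
        assert row["infinite"]
        assert np.isinf(row["fold_change"])

    def test_zero_member_total_rejected(self):
        ann = _ann([("t1", "host", "K", "P1", "")])
        tpm = pd.DataFrame([[0.0] * 4], index=["t1"], columns=SAMPLES)
        with pytest.raises(ValueError, match="host"):
            compute_qmf(tpm, ann, min_tpm=0, min_samples=0)


class TestCapabilityShares:
    def test_member_marginals(self):
        rows = [(f"h{i}", "host", "K", "P1", "") for i in range(10)]
        rows += [(f"s{i}", "symbiont", "K", "P1", "") for i in range(5)]
        rows += [(f"b{i}", "bacteria", "K", "P2", "") for i in range(5)]
        ann = _ann(rows)
        _, member = capability_shares(ann, [r[0] for r in rows])
        assert member["host"] == pytest.approx(0.5)
        assert member["symbiont"] == pytest.approx(0.25)
        assert member["bacteria"] == pytest.approx(0.25)

    def test_multi_pathway_counts_once_in_marginal(self):
        ann = _ann([("t1", "host", "K", "P1;P2", ""),
                    ("t2", "symbiont", "K", "P1", "")])
        table, member = capability_shares(ann, ["t1", "t2"])
        counts = table.set_index(["member", "pathway"])["count"]
        assert counts[("host", "P1")] == 1 and counts[("host", "P2")] == 1
        assert member["host"] == pytest.approx(0.5)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        members = ["host", "symbiont", "bacteria"]
        ann = _ann([
            (f"t{i}", members[rng.integers(3)], "K",
             ";".join(sorted(rng.choice([f"P{j}" for j in range(4)],
                             size=rng.integers(1, 3), replace=False))), "")
            for i in range(40)
        ])
        kept = [f"t{i}" for i in range(0, 40, 2)]
        table, member = capability_shares(ann, kept)
        annotated = [t for t in kept]
        total = len(annotated)
        for (m, p), c in table.set_index(["member", "pathway"])["count"].items():
            expected = sum(
                1 for t, mem, _, pws, _ in ann.itertuples(index=False)
                if t in kept and mem == m and p in pws.split(";")
            )
            assert c == expected
        assert member.sum() == pytest.approx(1.0)


class TestClassifyReactions:
    def test_definitions(self):
        ann = _ann([
            ("t1", "host", "K", "", "1.1.1.1;2.2.2.2"),
            ("t2", "symbiont", "K", "", "1.1.1.1"),
            ("t3", "bacteria", "K", "", "1.1.1.1"),
        ])
        part = classify_reactions(ann)
        table = part.table.set_index("ec")
        assert table.loc["1.1.1.1", "category"] == "multipartite"
        assert table.loc["2.2.2.2", "category"] == "unique"
        assert table.loc["2.2.2.2", "carriers"] == ("host",)

    def test_bipartite_pair_recorded(self):
        ann = _ann([("t1", "host", "K", "", "5.5.5.5"),
                    ("t2", "bacteria", "K", "", "5.5.5.5")])
        part = classify_reactions(ann)
        assert part.table.iloc[0]["pair"] == "bacteria-host"

    def test_random_designs_match_brute_force(self):
        rng = np.random.default_rng(6)
        members = ["host", "symbiont", "bacteria"]
        for _ in range(20):
            rows, truth = [], {}
            for e in range(12):
                ec = f"1.2.3.{e}"
                carriers = tuple(sorted(rng.choice(
                    members, size=rng.integers(1, 4), replace=False)))
                truth[ec] = carriers
                for i, m in enumerate(carriers):
                    rows.append((f"t{e}_{i}", m, "K", "", ec))
            part = classify_reactions(_ann(rows))
            table = part.table.set_index("ec")
            for ec, carriers in truth.items():
                assert table.loc[ec, "carriers"] == carriers
                assert table.loc[ec, "category"] == \
                    {1: "unique", 2: "bipartite", 3: "multipartite"}[len(carriers)]
            counts = part.counts()
            assert sum(counts.values()) == len(truth)

    def test_unexpressed_bucket_under_restriction(self):
        ann = _ann([("t1", "host", "K", "", "9.9.9.9")])
        part = classify_reactions(ann, kept_transcripts=[])
        assert part.table.empty
        assert part.unexpressed == ["9.9.9.9"]


class TestCategoryExpression:
    def test_all_unique_accounts_for_all_annotated_tpm(self):
        ann = _ann([("t1", "host", "K", "", "1.1.1.1"),
                    ("t2", "symbiont", "K", "", "2.2.2.2")])
        tpm = pd.DataFrame([[10.0] * 4, [30.0] * 4],
                           index=["t1", "t2"], columns=SAMPLES)
        part = classify_reactions(ann)
        out = category_expression(tpm, part, ann)
        assert (out["category"] == "unique").all()
        per_cond = out.groupby("condition")["tpm_total"].sum()
        assert (per_cond == 40.0).all()

    def test_empty_partition_empty_output(self):
        ann = _ann([("t1", "host", "K", "", "")])
        tpm = pd.DataFrame([[10.0] * 4], index=["t1"], columns=SAMPLES)
        part = classify_reactions(ann)
        out = category_expression(tpm, part, ann)
        assert out.empty

    def test_multi_category_transcript_counted_in_each_and_flagged(self):
        ann = _ann([
            ("t1", "host", "K", "", "1.1.1.1;2.2.2.2"),
            ("t2", "symbiont", "K", "", "1.1.1.1"),
        ])
        tpm = pd.DataFrame([[8.0] * 4, [2.0] * 4],
                           index=["t1", "t2"], columns=SAMPLES)
        part = classify_reactions(ann)  # 1.1.1.1 bipartite, 2.2.2.2 unique
        out = category_expression(tpm, part, ann)
        by_cat = out.groupby("category")["tpm_total"].sum()
        assert by_cat["bipartite"] == pytest.approx(2 * (8 + 2))
        assert by_cat["unique"] == pytest.approx(2 * 8)
        assert out.attrs["multi_category_transcripts"] == ["t1"]
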