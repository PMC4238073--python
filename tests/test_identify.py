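"""The tolerance-aware identification engine."""

import random

import pytest

from megakey import (
    GeneratorConfig,
    ToleranceConfig,
    Verdict,
    build_description,
    build_matrix,
    character_compatibility,
    generate_species,
    match,
    next_best_character,
    perturb_description,
)
from megakey.errors import ExhaustedKeyError, UsageError
from megakey.schema import (
    CharacterValue,
    character_ids,
    coded_letter,
    format_value,
    get_definition,
)


def cv(cid, raw):
    from megakey import encode_value
    return encode_value(cid, raw)


class TestCharacterCompatibility:
    def test_numeric_within_relative_window(self):
        d = get_definition("wing_length_mm")
        v = character_compatibility(cv("wing_length_mm", 1.60),
                                    cv("wing_length_mm", 1.56), d,
                                    ToleranceConfig(relative_tolerance=0.10))
        assert v is Verdict.COMPATIBLE  # |1.60-1.56| = 0.04 <= 0.156

    def test_numeric_outside_window(self):
        d = get_definition("wing_length_mm")
        v = character_compatibility(cv("wing_length_mm", 1.80),
                                    cv("wing_length_mm", 1.56), d,
                                    ToleranceConfig(relative_tolerance=0.10))
        assert v is Verdict.INCOMPATIBLE

    def test_window_anchored_on_reference_not_query(self):
        d = get_definition("wing_length_mm")
        tol = ToleranceConfig(relative_tolerance=0.10)
        # 1.10 vs ref 1.00: within 0.10; 1.00 vs ref 1.10 is the wider window
        assert character_compatibility(cv("wing_length_mm", 1.11),
                                       cv("wing_length_mm", 1.00), d, tol) \
            is Verdict.INCOMPATIBLE
        assert character_compatibility(cv("wing_length_mm", 1.00),
                                       cv("wing_length_mm", 1.11), d, tol) \
            is Verdict.COMPATIBLE

    def test_unknown_on_either_side_skips(self):
        d = get_definition("sps_vesicles")
        unk = CharacterValue("sps_vesicles", None)
        assert character_compatibility(cv("sps_vesicles", "present"), unk, d,
                                       ToleranceConfig()) \
            is Verdict.UNKNOWN_SKIPPED

    def test_open_count_bin_matches_any_high_count(self):
        d = get_definition("alular_setae_count")
        tol = ToleranceConfig()
        assert character_compatibility(cv("alular_setae_count", 7),
                                       cv("alular_setae_count", "4+"), d, tol) \
            is Verdict.COMPATIBLE
        assert character_compatibility(cv("alular_setae_count", 3),
                                       cv("alular_setae_count", "4+"), d, tol) \
            is Verdict.INCOMPATIBLE

    def test_count_slack(self):
        d = get_definition("alular_setae_count")
        assert character_compatibility(
            cv("alular_setae_count", 2), cv("alular_setae_count", 3), d,
            ToleranceConfig(absolute_count_tolerance=1)) is Verdict.COMPATIBLE

    def test_segment_ranges_must_be_identical(self):
        d = get_definition("ts1_palisade")
        assert character_compatibility(cv("ts1_palisade", "1-4"),
                                       cv("ts1_palisade", "1-3"), d,
                                       ToleranceConfig()) \
            is Verdict.INCOMPATIBLE

    def test_contradictory_setation_orders(self):
        d = get_definition("posterior_setation")
        assert character_compatibility(
            cv("posterior_setation", "T6~E~H<C"),
            cv("posterior_setation", "C<T6~E~H"), d,
            ToleranceConfig()) is Verdict.INCOMPATIBLE

    def test_mismatched_ids_are_a_usage_error(self):
        with pytest.raises(UsageError):
            character_compatibility(cv("sa_ratio", 1.0),
                                    cv("costal_index", 0.6),
                                    get_definition("sa_ratio"),
                                    ToleranceConfig())

    def test_per_character_override(self):
        d = get_definition("wing_length_mm")
        tol = ToleranceConfig(relative_tolerance=0.0,
                              overrides={"wing_length_mm": 0.5})
        assert character_compatibility(cv("wing_length_mm", 2.0),
                                       cv("wing_length_mm", 1.56), d, tol) \
            is Verdict.COMPATIBLE


class TestMatch:
    def test_identity_query_ranks_first_with_zero_mismatches(self, shadeae,
                                                             matrix50):
        m = build_matrix([shadeae, *matrix50.descriptions])
        res = match(shadeae, m)
        assert res[0].taxon_name == "Megaselia shadeae"
        assert res[0].mismatch_count == 0
        assert res[0].rank == 1

    def test_single_character_disagreement_counts_once(self, shadeae):
        m = build_matrix([shadeae])
        query = build_description("query", {"r2_3": "absent"})
        res = match(query, m)
        assert res[0].mismatch_count == 1
        assert res[0].verdicts["r2_3"] is Verdict.INCOMPATIBLE

    def test_perturbed_species_recovered_at_rank_one(self, fauna50, matrix50):
        target = fauna50[17]
        query = perturb_description(target, numeric_noise=0.05, flip_count=0,
                                    seed=7)
        res = match(query, matrix50)
        assert res[0].taxon_name == target.taxon_name

    def test_ranks_are_contiguous_from_one(self, fauna50, matrix50):
        query = perturb_description(fauna50[3], 0.05, 1, seed=3)
        res = match(query, matrix50)
        assert [r.rank for r in res] == list(range(1, len(matrix50) + 1))

    def test_empty_query_rejected(self, matrix50):
        with pytest.raises(UsageError):
            match(build_description("query", {}), matrix50)

    def test_over_budget_species_ranked_after_candidates(self, fauna50):
        m = build_matrix(fauna50[:10])
        query = perturb_description(fauna50[4], 0.0, 2, seed=11)
        res = match(query, m, ToleranceConfig(categorical_mismatch_budget=2))
        assert res[0].taxon_name == fauna50[4].taxon_name
        assert res[0].is_candidate
        non_candidates = [r.rank for r in res if not r.is_candidate]
        candidates = [r.rank for r in res if r.is_candidate]
        assert not non_candidates or max(candidates) < min(non_candidates)

    def test_monotonicity_in_tolerance(self, fauna50):
        m = build_matrix(fauna50[:15])
        query = perturb_description(fauna50[8], 0.08, 0, seed=2)
        previous = None
        for tol in (0.0, 0.02, 0.05, 0.10, 0.25):
            res = {r.taxon_name: r.mismatch_count
                   for r in match(query, m, ToleranceConfig(tol))}
            if previous is not None:
                assert all(res[name] <= previous[name] for name in res)
            previous = res

    def test_unknowns_are_neutral(self, shadeae, fauna50):
        m = build_matrix([shadeae, *fauna50[:5]])
        partial = build_description("q", {"r2_3": "present",
                                          "wing_length_mm": 1.56})
        padded = build_description("q", {"r2_3": "present",
                                         "wing_length_mm": 1.56,
                                         **{cid: "?" for cid in
                                            ("sa_ratio", "np_cleft",
                                             "posterior_setation")}})
        ra, rb = match(partial, m), match(padded, m)
        for a, b in zip(ra, rb):
            assert (a.taxon_name, a.verdicts) == (b.taxon_name, b.verdicts)


class TestZeroToleranceOracle:
    @staticmethod
    def order_ranks(expr):
        """Token ranks brute-forced from the rendered expression text."""
        ranks = {}
        for i, group in enumerate(expr.replace("~", "=").split("<")):
            for tok in group.split("="):
                ranks[tok] = i
        return ranks

    @classmethod
    def oracle_rank(cls, query, descriptions):
        """Brute-force exact-equality oracle over serialized cell forms
        (ordering expressions compare by enumerating all pairwise order
        constraints, the semantics the engine documents)."""
        rows = []
        for d in descriptions:
            mism = unk = 0
            for cid in character_ids():
                q, r = query.values[cid].value, d.values[cid].value
                if q is None or r is None:
                    unk += 1
                    continue
                defn = get_definition(cid)
                if defn.kind in ("coded_categorical", "count"):
                    equal = coded_letter(cid, q) == coded_letter(cid, r)
                elif defn.kind == "order_expression":
                    ra = cls.order_ranks(str(q))
                    rb = cls.order_ranks(str(r))
                    equal = not any(
                        (ra[x] - ra[y]) * (rb[x] - rb[y]) < 0
                        for x in ra for y in ra if x != y)
                else:
                    equal = format_value(cid, q) == format_value(cid, r)
                mism += not equal
            rows.append((mism, unk, d.taxon_name))
        rows.sort()
        return rows

    def test_engine_equals_oracle_on_20_random_cases(self):
        rng = random.Random(20141112)
        zero = ToleranceConfig(relative_tolerance=0.0,
                               absolute_count_tolerance=0,
                               categorical_mismatch_budget=0)
        for case in range(20):
            fauna = generate_species(GeneratorConfig(
                n_species=6, seed=rng.randrange(2**31),
                min_pairwise_separation=1))
            base = rng.choice(fauna)
            query = perturb_description(base, 0.0,
                                        flip_count=rng.randrange(3),
                                        seed=rng.randrange(2**31))
            # hide a random subset of characters
            hidden = rng.sample(character_ids(), k=rng.randrange(0, 20))
            values = dict(query.values)
            for cid in hidden:
                values[cid] = CharacterValue(cid, None)
            query = build_description("q", values)
            expected = self.oracle_rank(query, fauna)
            got = [(r.mismatch_count, r.unknown_count, r.taxon_name)
                   for r in match(query, build_matrix(fauna), zero)]
            assert got == expected, f"case {case}"


class TestNextBestCharacter:
    def toy_matrix(self):
        """3 species differing in a 3-state, a 2-state and a constant character.

        Hand-computed survivor-state entropies: scutellar setae (codes
        a/b/c) = log2 3 ~ 1.585; SPS vesicles (a/b/b) ~ 0.918;
        NP cleft (a/a/a) = 0.
        """
        base = {"np_cleft": "absent", "sps_vesicles": "absent"}
        rows = []
        for i, (scut, sps) in enumerate([("4 =", "absent"),
                                         ("4 /=", "present"),
                                         ("2+2", "present")]):
            rows.append(build_description(
                f"sp{i}", {**base, "scutellar_setae": scut,
                           "sps_vesicles": sps}))
        return build_matrix(rows)

    def test_max_entropy_character_wins(self):
        m = self.toy_matrix()
        answered = set(character_ids()) - {"scutellar_setae", "sps_vesicles",
                                           "np_cleft"}
        assert next_best_character(m, set(m.species), answered) \
            == "scutellar_setae"

    def test_only_informative_character_is_chosen(self, fauna50):
        rows = [build_description(f"s{i}", {"np_setae_count": v,
                                            "np_cleft": "absent"})
                for i, v in enumerate(["2", "3"])]
        m = build_matrix(rows)
        answered = set(character_ids()) - {"np_setae_count", "np_cleft"}
        assert next_best_character(m, set(m.species), answered) \
            == "np_setae_count"

    def test_exhausted_when_survivors_identical(self):
        rows = [build_description(f"s{i}", {"np_cleft": "absent"})
                for i in range(2)]
        m = build_matrix(rows)
        answered = set(character_ids()) - {"np_cleft"}
        with pytest.raises(ExhaustedKeyError):
            next_best_character(m, set(m.species), answered)

    def test_exhausted_when_no_character_left(self):
        rows = [build_description(f"s{i}", {"np_cleft": v})
                for i, v in enumerate(["absent", "present"])]
        m = build_matrix(rows)
        with pytest.raises(ExhaustedKeyError):
            next_best_character(m, set(m.species), set(character_ids()))

    def test_numeric_binning_ignores_within_tolerance_spread(self):
        # wing lengths 2% apart fall in one tolerance-width bin at 10%
        rows = [build_description(f"s{i}", {"wing_length_mm": w,
                                            "np_cleft": c})
                for i, (w, c) in enumerate([(1.50, "absent"),
                                            (1.52, "present")])]
        m = build_matrix(rows)
        answered = set(character_ids()) - {"wing_length_mm", "np_cleft"}
        assert next_best_character(m, set(m.species), answered) == "np_cleft"
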