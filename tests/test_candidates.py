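import logging

import numpy as np
import pytest

from chemrel.candidates import (batch_instances, build_document_instances,
                                build_instance, entity_token_indices,
                                enumerate_pairs, instances_to_jsonl,
                                label_candidate)
from chemrel.corpus import (Abstract, CprGroup, EntityKind, EntityMention,
                            RelationGold)
from chemrel.tokenize import TokenSpan, overlap_flags, tokenize_with_spans
from chemrel.vocab import (MASK_BOTH, MASK_CHEMICAL, MASK_PROTEIN, UNK,
                           build_vocab)


def _make_doc(n_tokens, entity_positions):
    """Single-character tokens at positions 0,2,4,...; entities on token spans.

    ``entity_positions``: list of (kind, first_token, last_token).
    """
    tokens = [TokenSpan(chr(97 + i % 26), 2 * i, 2 * i + 1)
              for i in range(n_tokens)]
    ents = []
    for k, (kind, ft, lt) in enumerate(entity_positions):
        ents.append(EntityMention("D", f"T{k + 1}", kind,
                                  tokens[ft].char_start, tokens[lt].char_end,
                                  "x"))
    return tokens, ents


CHEM, GENE = EntityKind.CHEMICAL, EntityKind.GENE


class TestEnumeratePairs:
    def test_beyond_window_excluded(self):
        tokens, ents = _make_doc(80, [(CHEM, 0, 0), (GENE, 70, 70)])
        assert enumerate_pairs(tokens, ents, max_distance=60) == []

    def test_multi_token_distance(self):
        tokens, ents = _make_doc(20, [(CHEM, 3, 4), (GENE, 10, 10)])
        assert len(enumerate_pairs(tokens, ents, max_distance=7)) == 1
        assert enumerate_pairs(tokens, ents, max_distance=6) == []

    def test_cartesian_count(self):
        tokens, ents = _make_doc(30, [(CHEM, 0, 0), (CHEM, 5, 5),
                                      (GENE, 10, 10), (GENE, 15, 15),
                                      (GENE, 20, 20)])
        assert len(enumerate_pairs(tokens, ents)) == 6

    def test_gene_before_chemical_allowed(self):
        tokens, ents = _make_doc(20, [(GENE, 2, 2), (CHEM, 8, 8)])
        pairs = enumerate_pairs(tokens, ents, max_distance=6)
        assert len(pairs) == 1
        chem, gene = pairs[0]
        assert chem.kind is CHEM and gene.kind is GENE

    def test_entity_without_token_skipped(self, caplog):
        tokens, ents = _make_doc(10, [(CHEM, 0, 0), (GENE, 5, 5)])
        # entity span in a whitespace gap: overlaps no token
        ents.append(EntityMention("D", "T9", GENE, 1, 2, "?"))
        with caplog.at_level(logging.WARNING):
            pairs = enumerate_pairs(tokens, ents)
        assert len(pairs) == 1
        assert "overlaps no token" in caplog.text

    def test_brute_force_oracle_on_synthetic_docs(self, small_synth):
        """enumerate_pairs agrees with a literal scan of all pairs."""
        _, (abstracts, entities, _) = small_synth
        for ab in abstracts:
            tokens = tokenize_with_spans(ab.text)
            ents = [e for e in entities if e.doc_id == ab.doc_id]
            got = {(c.entity_id, g.entity_id)
                   for c, g in enumerate_pairs(tokens, ents, max_distance=60)}
            expected = set()
            member = {e.entity_id: [i for i, t in enumerate(tokens)
                                    if overlap_flags(t, e).any] for e in ents}
            for c in ents:
                for g in ents:
                    if c.kind is not CHEM or g.kind is not GENE:
                        continue
                    ci, gi = member[c.entity_id], member[g.entity_id]
                    if not ci or not gi:
                        continue
                    if (ci[0], c.char_start) <= (gi[0], g.char_start):
                        dist = gi[-1] - ci[0]
                    else:
                        dist = ci[-1] - gi[0]
                    if dist <= 60:
                        expected.add((c.entity_id, g.entity_id))
            assert got == expected


class TestBuildInstance:
    def _vocab(self):
        return build_vocab([[chr(97 + i) for i in range(26)] * 2])

    def test_window_clipped_at_document_start(self):
        tokens, ents = _make_doc(20, [(CHEM, 3, 3), (GENE, 10, 10)])
        inst = build_instance(tokens, ents, ents[0], ents[1], self._vocab())
        # 3 - 5 clips to 0; 10 + 5 = 15; inclusive -> 16 positions
        assert len(inst) == 16

    def test_masks_and_pair_features(self):
        tokens, ents = _make_doc(12, [(CHEM, 2, 3), (GENE, 6, 6)])
        vocab = self._vocab()
        inst = build_instance(tokens, ents, ents[0], ents[1], vocab)
        ids = inst.token_ids
        # multi-token chemical: one mask per original token
        assert ids[2] == MASK_CHEMICAL and ids[3] == MASK_CHEMICAL
        assert ids[6] == MASK_PROTEIN
        np.testing.assert_array_equal(inst.pair_features[2], [1, 0])
        np.testing.assert_array_equal(inst.pair_features[6], [0, 1])
        # non-entity tokens go through the vocabulary
        assert ids[0] == vocab[tokens[0].surface]

    def test_both_mask_when_chem_and_gene_coincide(self):
        tokens, _ = _make_doc(8, [])
        chem = EntityMention("D", "T1", CHEM, tokens[3].char_start,
                             tokens[3].char_end, "x")
        gene = EntityMention("D", "T2", GENE, tokens[3].char_start,
                             tokens[3].char_end, "x")
        inst = build_instance(tokens, [chem, gene], chem, gene, self._vocab())
        j = 3  # window starts at token 0 (3 - 5 clipped)
        assert inst.token_ids[j] == MASK_BOTH
        np.testing.assert_array_equal(inst.pair_features[j], [1, 1])

    def test_context_features_see_all_entities_pair_features_only_candidate(self):
        tokens, ents = _make_doc(14, [(CHEM, 2, 2), (GENE, 8, 8),
                                      (CHEM, 5, 5)])
        inst = build_instance(tokens, ents, ents[0], ents[1], self._vocab())
        j = 5  # window starts at 0
        assert inst.entity_context_features[j, :5].any()   # chemical bits set
        np.testing.assert_array_equal(inst.pair_features[j], [0, 0])
        # the bystander chemical is not masked
        assert inst.token_ids[j] not in (MASK_CHEMICAL, MASK_BOTH)

    def test_invariants_on_synthetic_corpus(self, small_synth, small_vocab):
        cfg, (abstracts, entities, gold) = small_synth
        for ab in abstracts:
            for inst in build_document_instances(ab, entities, gold,
                                                 small_vocab):
                t = len(inst.token_ids)
                assert inst.entity_context_features.shape == (t, 10)
                assert inst.pair_features.shape == (t, 2)
                chem_bit = inst.pair_features[:, 0].astype(bool)
                gene_bit = inst.pair_features[:, 1].astype(bool)
                assert all(inst.token_ids[i] in (MASK_CHEMICAL, MASK_BOTH)
                           for i in np.flatnonzero(chem_bit))
                assert all(inst.token_ids[i] in (MASK_PROTEIN, MASK_BOTH)
                           for i in np.flatnonzero(gene_bit))


class TestLabelCandidate:
    def _pair(self):
        chem = EntityMention("D", "T1", CHEM, 0, 1, "c")
        gene = EntityMention("D", "T2", GENE, 2, 3, "g")
        return chem, gene

    def test_no_gold_is_none(self):
        chem, gene = self._pair()
        assert label_candidate(chem, gene, []) == 0

    @pytest.mark.parametrize("group,expected", [
        (CprGroup.CPR3, 1), (CprGroup.CPR4, 2), (CprGroup.CPR5, 3),
        (CprGroup.CPR6, 4), (CprGroup.CPR9, 5),
    ])
    def test_group_index_map(self, group, expected):
        chem, gene = self._pair()
        gold = [RelationGold("D", group, "T1", "T2")]
        assert label_candidate(chem, gene, gold) == expected

    def test_multiple_groups_resolve_to_lowest_with_warning(self, caplog):
        chem, gene = self._pair()
        gold = [RelationGold("D", CprGroup.CPR9, "T1", "T2"),
                RelationGold("D", CprGroup.CPR3, "T1", "T2")]
        with caplog.at_level(logging.WARNING):
            assert label_candidate(chem, gene, gold) == 1
        assert "gold groups" in caplog.text

    def test_nonzero_instances_match_gold_within_window(self, small_synth,
                                                        small_vocab):
        """Every generated relation is recovered as a labelled candidate."""
        _, (abstracts, entities, gold) = small_synth
        instances = []
        for ab in abstracts:
            instances.extend(build_document_instances(ab, entities, gold,
                                                      small_vocab))
        assert sum(1 for i in instances if i.label != 0) == len(gold)


class TestBatching:
    def test_batches_align_with_indices_and_conserve(self, small_synth,
                                                     small_vocab):
        _, (abstracts, entities, gold) = small_synth
        instances = []
        for ab in abstracts[:5]:
            instances.extend(build_document_instances(ab, entities, gold,
                                                      small_vocab))
        batches = batch_instances(instances, batch_size=8)
        seen = np.concatenate([b.indices for b in batches])
        assert sorted(seen.tolist()) == list(range(len(instances)))
        for b in batches:
            assert b.token_ids.shape[0] == len(b.indices) <= 8
            for row, idx in enumerate(b.indices):
                inst = instances[idx]
                np.testing.assert_array_equal(
                    b.token_ids[row, :len(inst)], inst.token_ids)
                assert b.labels[row] == inst.label

    def test_jsonl_debug_dump(self, tmp_path, small_synth, small_vocab):
        _, (abstracts, entities, gold) = small_synth
        instances = build_document_instances(abstracts[0], entities, gold,
                                             small_vocab)
        path = tmp_path / "debug.jsonl"
        instances_to_jsonl(instances, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(instances)
        assert "$CHEMICAL" in lines[0] or "$PROTEIN" in lines[0]
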