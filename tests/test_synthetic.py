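import numpy as np
import pytest

from chemrel.candidates import build_document_instances, enumerate_pairs
from chemrel.corpus import (CprGroup, read_abstracts, read_entities,
                            read_glove, read_gold_relations)
from chemrel.synthetic import (SynthConfig, generate_corpus,
                               generate_pretrain_text, generate_toy_glove,
                               token_inventory, write_corpus_files)
from chemrel.tokenize import tokenize_with_spans


class TestGenerateCorpus:
    def test_counts_and_determinism(self, small_synth):
        cfg, (abstracts, entities, relations) = small_synth
        assert len(abstracts) == cfg.n_abstracts
        again = generate_corpus(cfg, seed=123)
        assert again == (abstracts, entities, relations)

    def test_written_files_are_byte_identical_across_runs(self, tmp_path,
                                                          small_synth):
        cfg, records = small_synth
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_corpus_files(d1, *records)
        write_corpus_files(d2, *generate_corpus(cfg, seed=123))
        for name in ("abstracts.tsv", "entities.tsv", "relations.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_offsets_survive_strict_reading(self, tmp_path, small_synth):
        _, records = small_synth
        paths = write_corpus_files(tmp_path, *records)
        abstracts = read_abstracts(paths["abstracts"])
        entities = read_entities(paths["entities"], abstracts, strict=True)
        relations = read_gold_relations(paths["relations"], entities,
                                        strict=True)
        assert (abstracts, entities, relations) == records

    def test_disjoint_triggers_enforced(self):
        bad = dict(SynthConfig().triggers)
        bad[CprGroup.CPR3] = bad[CprGroup.CPR3] + bad[CprGroup.CPR4][:1]
        with pytest.raises(ValueError, match="disjoint"):
            SynthConfig(triggers=bad)

    def test_relations_within_candidate_window(self, small_synth):
        """Every gold pair passes the 60-token distance filter."""
        _, (abstracts, entities, relations) = small_synth
        for ab in abstracts:
            tokens = tokenize_with_spans(ab.text)
            ents = [e for e in entities if e.doc_id == ab.doc_id]
            pairs = {(c.entity_id, g.entity_id)
                     for c, g in enumerate_pairs(tokens, ents)}
            for rel in relations:
                if rel.doc_id == ab.doc_id:
                    assert (rel.chem_id, rel.gene_id) in pairs

    def test_trigger_oracle_reaches_ceiling(self, small_synth, small_vocab):
        """Label is a function of the trigger word: a trigger-lookup
        classifier recovers every gold relation exactly (F = 100)."""
        cfg, (abstracts, entities, gold) = small_synth
        trigger_to_label = {t: g.label_index
                            for g, ts in cfg.triggers.items() for t in ts}
        predicted, actual = [], []
        for ab in abstracts:
            for inst in build_document_instances(ab, entities, gold,
                                                 small_vocab):
                surfaces = inst.masked_surfaces
                chem_pos = [i for i, s in enumerate(surfaces)
                            if s in ("$CHEMICAL", "$BOTH")]
                gene_pos = [i for i, s in enumerate(surfaces)
                            if s in ("$PROTEIN", "$BOTH")]
                lab = 0
                if chem_pos and gene_pos and max(chem_pos) < min(gene_pos):
                    between = surfaces[max(chem_pos) + 1:min(gene_pos)]
                    # generative pattern: chemical [adverb] trigger protein
                    if (1 <= len(between) <= 2
                            and between[-1] in trigger_to_label
                            and all(w in ("strongly", "markedly")
                                    for w in between[:-1])):
                        lab = trigger_to_label[between[-1]]
                predicted.append(lab)
                actual.append(inst.label)
        assert predicted == actual


class TestPretrainText:
    def test_line_count_and_determinism(self):
        lines = generate_pretrain_text(100, seed=4)
        assert len(lines) == 100
        assert lines == generate_pretrain_text(100, seed=4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            generate_pretrain_text(0, seed=1)

    def test_inventory_shared_with_corpus(self):
        cfg = SynthConfig()
        inventory = set(token_inventory(cfg))
        for line in generate_pretrain_text(50, seed=4, cfg=cfg):
            assert set(line.split()) <= inventory

    def test_bigrams_far_from_independence(self):
        """The grammar's transitions are strongly non-uniform: the bigram
        chi-squared statistic exceeds the independence expectation by far."""
        cfg = SynthConfig()
        inventory = token_inventory(cfg)
        index = {t: i for i, t in enumerate(inventory)}
        n = len(inventory)
        counts = np.zeros((n, n))
        for line in generate_pretrain_text(1500, seed=4, cfg=cfg):
            toks = [index[t] for t in line.split()]
            for a, b in zip(toks, toks[1:]):
                counts[a, b] += 1
        total = counts.sum()
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        expected = row @ col / total
        mask = expected > 0
        chi2 = ((counts - expected)[mask] ** 2 / expected[mask]).sum()
        dof = (n - 1) ** 2
        # under independence chi2 ~ dof +- sqrt(2 dof); require a wide margin
        assert chi2 > dof + 20 * np.sqrt(2 * dof)


class TestToyGlove:
    def test_format_and_roundtrip(self, tmp_path):
        tokens = ["a", "b", "c", "d", "e"]
        path = tmp_path / "glove.txt"
        lines = generate_toy_glove(tokens, dim=3, seed=2, path=path)
        assert len(lines) == 5
        assert all(len(l.split()) == 4 for l in lines)
        table = read_glove(path, expected_dim=3)
        assert len(table) == 5
        assert all(np.abs(table[t]).max() <= 1.0 for t in tokens)

    def test_deterministic(self):
        assert (generate_toy_glove(["x", "y"], 4, seed=9)
                == generate_toy_glove(["x", "y"], 4, seed=9))
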