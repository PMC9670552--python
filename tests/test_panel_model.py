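"""Domain types, panel configuration, and cohort I/O."""

import json

import pytest
import yaml

from gliopanel.errors import ConfigError, ParseError
from gliopanel.panel_model import (
    CaseRecord,
    CopyNumberProfile,
    FishEGFR,
    ModalityResults,
    SequenceVariant,
    default_panel_map,
    load_panel_map,
    read_cohort,
    read_report,
    write_report,
)
from gliopanel.synthetic_cohort import simulate_cohort, write_cohort_dir

from conftest import small_config

EXPECTED_ARM_SETS = {
    "arm_1p": {"MTOR", "MYCL", "MPL", "MAGOH", "JAK1", "NRAS"},
    "arm_1q": {"BCL9", "MCL1", "DDR2", "MDM4"},
    "arm_19p": {"STK11", "GNA11", "MAP2K2", "JAK3"},
    "arm_19q": {"CCNE1", "PPP2R1A"},
}


@pytest.mark.parametrize("name,genes", sorted(EXPECTED_ARM_SETS.items()))
def test_default_panel_arm_groups_match_assay_design(panel, name, genes):
    assert set(panel.arm_sets[name]) == genes


def _default_panel_yaml() -> dict:
    from importlib import resources

    return yaml.safe_load(resources.files("gliopanel.data").joinpath("panel.yaml").read_text())


def test_custom_chr7_background_gene_passes_through(tmp_path):
    cfg = _default_panel_yaml()
    cfg["genes"]["KMT2C"] = {"chromosome": "7", "arm": "q"}
    cfg["arm_sets"]["chr7_background"] = list(cfg["arm_sets"]["chr7_background"]) + ["KMT2C"]
    path = tmp_path / "panel.yaml"
    path.write_text(yaml.safe_dump(cfg))
    pm = load_panel_map(path)
    assert "KMT2C" in pm.arm_sets["chr7_background"]
    for name, genes in EXPECTED_ARM_SETS.items():
        assert set(pm.arm_sets[name]) == genes  # other groups unchanged


@pytest.mark.parametrize(
    "mutate,err",
    [
        (lambda c: c["arm_sets"].__setitem__("arm_1p", []), ConfigError),
        (lambda c: c["arm_sets"].pop("arm_19q"), ConfigError),
        (lambda c: c["genes"].__setitem__("MTOR", {"chromosome": "chr1", "arm": "p"}), ParseError),
        (lambda c: c["arm_sets"].__setitem__("arm_1p", ["NOSUCHGENE"]), ConfigError),
    ],
)
def test_malformed_panel_config_rejected(tmp_path, mutate, err):
    cfg = _default_panel_yaml()
    mutate(cfg)
    path = tmp_path / "panel.yaml"
    path.write_text(yaml.safe_dump(cfg))
    with pytest.raises(err):
        load_panel_map(path)


# ---------------------------------------------------------------------------
# domain type invariants
# ---------------------------------------------------------------------------


def test_negative_copy_number_rejected():
    with pytest.raises(ValueError):
        CopyNumberProfile(case_id="x", entries={"EGFR": -0.5})


@pytest.mark.parametrize(
    "change,vclass,ok",
    [
        ("R132H", "missense", True),
        ("R132H", "nonsense", False),
        ("R196*", "nonsense", True),
        ("P72fs", "frameshift", True),
        ("N131del", "inframe_del", True),
        ("N131del", "frameshift", True),  # del notation is ambiguous between the two
        ("c.559+1G>A", "splice_site", True),  # unparseable protein notation: no check
        ("R196*", "missense", False),
    ],
)
def test_variant_class_consistency_with_protein_notation(change, vclass, ok):
    if ok:
        SequenceVariant(gene="TP53", protein_change=change, variant_class=vclass)
    else:
        with pytest.raises(ValueError):
            SequenceVariant(gene="TP53", protein_change=change, variant_class=vclass)


def test_fish_egfr_amplified_flag_must_match_numeric_rule():
    FishEGFR(mean_egfr_signals=10.0, egfr_cep7_ratio=5.0, amplified=True)
    FishEGFR(mean_egfr_signals=3.0, egfr_cep7_ratio=1.1, amplified=False)
    with pytest.raises(ValueError):
        FishEGFR(mean_egfr_signals=10.0, egfr_cep7_ratio=5.0, amplified=False)
    with pytest.raises(ValueError):
        FishEGFR(mean_egfr_signals=3.0, egfr_cep7_ratio=1.1, amplified=True)


@pytest.mark.parametrize("age,expected", [(5, True), (20.9, True), (21.0, False), (70, False), (None, None)])
def test_pediatric_flag_below_21_years(age, expected):
    assert CaseRecord(case_id="x", age_years=age).pediatric is expected


# ---------------------------------------------------------------------------
# cohort reading
# ---------------------------------------------------------------------------


def _write(path, header, rows):
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]) + "\n")


CN_HEADER = ["case_id", "gene", "chromosome", "arm", "copy_number"]


def test_read_cohort_counts_and_join(tmp_path, panel):
    _write(tmp_path / "cn.tsv", CN_HEADER, [
        ["c1", "MTOR", "1", "p", "1.1"],
        ["c1", "NRAS", "1", "p", "1.2"],
        ["c1", "CCNE1", "19", "q", "1.3"],
        ["c2", "MTOR", "1", "p", "2.0"],
        ["c2", "NRAS", "1", "p", "2.1"],
        ["c2", "CCNE1", "19", "q", "2.2"],
    ])
    _write(tmp_path / "variants.tsv",
           ["case_id", "gene", "protein_change", "variant_class", "origin"],
           [["c1", "IDH1", "R132H", "missense", "somatic"],
            ["c3", "TP53", "R273H", "missense", "somatic"]])  # c3 has no CN rows
    cases = read_cohort(tmp_path, panel)
    by_id = {c.case_id: c for c in cases}
    assert set(by_id) == {"c1", "c2", "c3"}
    assert len(by_id["c1"].cn_profile) == 3 and len(by_id["c2"].cn_profile) == 3
    # IHC-only/variant-only case still creates a record, with empty CN profile
    assert len(by_id["c3"].cn_profile) == 0
    assert by_id["c3"].variants[0].gene == "TP53"
    # row conservation: every input row landed in exactly one record
    assert sum(len(c.cn_profile) for c in cases) == 6
    assert sum(len(c.variants) for c in cases) == 2
    # cases absent from modalities get not_done defaults
    assert by_id["c1"].modalities.ihc_p53_score == "not_done"


def test_duplicate_cn_row_is_an_error_naming_the_case_and_gene(tmp_path, panel):
    _write(tmp_path / "cn.tsv", CN_HEADER, [
        ["c1", "EGFR", "7", "p", "2.0"],
        ["c1", "EGFR", "7", "p", "2.1"],
    ])
    with pytest.raises(ParseError, match="EGFR"):
        read_cohort(tmp_path, panel)


def test_unparseable_copy_number_is_an_error(tmp_path, panel):
    _write(tmp_path / "cn.tsv", CN_HEADER, [["c1", "EGFR", "7", "p", "two"]])
    with pytest.raises(ParseError, match="unparseable"):
        read_cohort(tmp_path, panel)


def test_synthetic_roundtrip_through_tsv(tmp_path, panel):
    sim = simulate_cohort(small_config(), seed=11)
    write_cohort_dir(sim, tmp_path, panel_map=panel)
    cases = read_cohort(tmp_path, panel)
    assert len(cases) == len(sim.cases)
    orig = {c.case_id: c for c in sim.cases}
    for case in cases:
        ref = orig[case.case_id]
        assert set(case.cn_profile.entries) == set(ref.cn_profile.entries)
        for gene, cn in case.cn_profile.entries.items():
            assert cn == pytest.approx(ref.cn_profile.entries[gene], abs=1e-4)
        assert len(case.variants) == len(ref.variants)
        assert case.modalities.ihc_p53_score == ref.modalities.ihc_p53_score
        assert case.modalities.rna_qc == ref.modalities.rna_qc


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def test_report_json_roundtrip_and_schema(tmp_path):
    from gliopanel.pipeline import call_cohort

    sim = simulate_cohort(small_config(n_oligo=1, n_mut=0, n_wt=0, n_pilo=0, n_other=0), seed=3)
    calls = call_cohort(sim.cases)
    path = tmp_path / "report.json"
    write_report(calls, path)
    back = read_report(path)
    assert len(back) == 1
    assert set(back[0]) >= {"case_id", "codel", "egfr", "cdkn2a", "idh", "tp53",
                            "atrx_prediction", "fusions", "integrated"}
    assert back == json.loads(json.dumps(calls))  # identical structure

    empty = tmp_path / "empty.json"
    write_report([], empty)
    assert read_report(empty) == []


def test_report_tsv_summary(tmp_path):
    from gliopanel.pipeline import call_cohort

    sim = simulate_cohort(small_config(), seed=3)
    calls = call_cohort(sim.cases)
    path = tmp_path / "summary.tsv"
    write_report(calls, path, format="tsv")
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert len(df) == len(calls)
    assert "case_id" in df.columns
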