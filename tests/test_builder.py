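"""Graft building, PIR alignments, assembly, and the full pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrpmhc.builder import (
    ModellingJob,
    Stage,
    assemble_complex,
    build_alignment_file,
    extract_submodel,
    graft_build,
    model_pmhc,
    model_tcr,
    parse_alignment_file,
    register_backend,
    run_pipeline,
)
from tcrpmhc.core import (
    BackendError,
    ContractError,
    InputError,
    Kind,
    Role,
)
from tcrpmhc.metrics import Component, component_rmsd
from tcrpmhc.selection import (
    SelectionConfig,
    query_from_entry,
    select_templates,
)
from tcrpmhc.structio import write_fasta


def _selection_for(db, target_id, **config_kwargs):
    entry = db.entries[target_id]
    return select_templates(
        query_from_entry(entry), db, SelectionConfig(**config_kwargs)
    )


def _job(db, target_id, stage, selection=None):
    entry = db.entries[target_id]
    selection = selection or _selection_for(db, target_id)
    return ModellingJob(
        target_sequences=entry.structure.sequences(),
        stage=stage,
        selection=selection,
        templates={cid: db.entries[cid] for cid in selection.chosen},
        profiles=db.profiles,
    )


class TestAlignmentFile:
    def test_identical_template_gap_free(self, isolated_universe):
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        entry = db.entries[eid]
        text = build_alignment_file(
            entry.structure.sequences(), [entry], db.profiles, Kind.PMHC
        )
        records = parse_alignment_file(text)
        assert set(records) == {"target", eid}
        assert "-" not in "".join(records["target"])
        assert records["target"] == records[eid]

    def test_round_trip_preserves_column_mapping(self, isolated_universe):
        db = isolated_universe["tcrpmhc"]
        ids = db.ids()[:2]
        entry = db.entries[ids[0]]
        text = build_alignment_file(
            entry.structure.sequences(),
            [db.entries[i] for i in ids],
            db.profiles,
            Kind.TCRPMHC,
        )
        records = parse_alignment_file(text)
        widths = {tuple(len(b) for b in blocks) for blocks in records.values()}
        assert len(widths) == 1  # all records share the same column layout

    def test_peptide_length_mismatch_rejected(self, universe):
        db = universe["tcrpmhc"]
        by_len = {}
        for eid in db.ids():
            by_len.setdefault(db.entries[eid].peptide_length, eid)
        (l1, e1), (l2, e2) = list(by_len.items())[:2]
        with pytest.raises(InputError):
            build_alignment_file(
                db.entries[e1].structure.sequences(),
                [db.entries[e2]],
                db.profiles,
                Kind.TCRPMHC,
            )


class TestGraft:
    def test_single_identical_template_reproduces_coordinates(
        self, isolated_universe
    ):
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        model = graft_build(_job(db, eid, Stage.PMHC))
        native = db.entries[eid].structure
        assert model.templates_used == [eid]
        assert component_rmsd(
            model.structure, native, Component.PMHC
        ) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_templates_average_to_same_shape(
        self, isolated_universe
    ):
        """Two templates that are rigid-body copies of each other yield a
        model with RMSD 0 to either after superposition."""
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        selection = _selection_for(db, eid)
        entry = db.entries[eid]
        twin = db.entries[eid]
        # manufacture the twin: same entry under a new id, rigidly moved
        import copy as _copy

        from tcrpmhc.templatedb import TemplateEntry

        moved = entry.structure.copy(new_id="twin")
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        moved.transform(R, np.array([5.0, -3.0, 11.0]))
        twin_entry = TemplateEntry(
            structure=moved, alignments=_copy.deepcopy(entry.alignments)
        )
        selection.ranked = [
            c for c in selection.ranked if c.id == eid
        ]
        twin_cand = _copy.deepcopy(selection.ranked[0])
        twin_cand.id = "twin"
        selection.ranked.append(twin_cand)
        selection.chosen = [eid, "twin"]
        job = ModellingJob(
            target_sequences=entry.structure.sequences(),
            stage=Stage.PMHC,
            selection=selection,
            templates={eid: entry, "twin": twin_entry},
            profiles=db.profiles,
        )
        model = graft_build(job)
        assert component_rmsd(
            model.structure, entry.structure, Component.PMHC
        ) == pytest.approx(0.0, abs=1e-6)

    def test_mutated_residue_gets_backbone_but_no_side_chain(
        self, isolated_universe
    ):
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        entry = db.entries[eid]
        seqs = entry.structure.sequences()
        pep = list(seqs[Role.PEPTIDE])
        original = pep[2]
        pep[2] = "W" if original != "W" else "Y"
        seqs[Role.PEPTIDE] = "".join(pep)
        selection = _selection_for(db, eid)
        job = ModellingJob(
            target_sequences=seqs,
            stage=Stage.PMHC,
            selection=selection,
            templates={cid: db.entries[cid] for cid in selection.chosen},
            profiles=db.profiles,
        )
        model = graft_build(job)
        res = model.structure.chain(Role.PEPTIDE).residues[2]
        assert set(res.atoms) == {"N", "CA", "C", "O"}  # no copied CB

    def test_no_template_coverage_is_error(self, isolated_universe):
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        selection = _selection_for(db, eid)
        entry = db.entries[eid]
        # cripple the only chosen template: drop 60% of its MHC residues
        from tcrpmhc.templatedb import TemplateEntry

        crippled = entry.structure.copy()
        chain = crippled.chain(Role.MHC)
        chain.residues = chain.residues[: int(len(chain) * 0.4)]
        chain.reindex()
        import copy as _copy

        from tcrpmhc.core import InsufficientTemplateError
        from tcrpmhc.profiles import align_to_profile

        alns = _copy.deepcopy(entry.alignments)
        alns[Role.MHC] = align_to_profile(
            chain.sequence, db.profiles[Role.MHC]
        )
        selection.ranked = [c for c in selection.ranked if c.id == eid]
        selection.chosen = [eid]
        job = ModellingJob(
            target_sequences=entry.structure.sequences(),
            stage=Stage.PMHC,
            selection=selection,
            templates={eid: TemplateEntry(structure=crippled, alignments=alns)},
            profiles=db.profiles,
        )
        with pytest.raises(InsufficientTemplateError):
            graft_build(job)


class TestStageDrivers:
    def test_model_pmhc_picks_engineered_best(self, universe):
        db = universe["pmhc"]
        manifest = universe["manifest"]
        info = manifest["probes"]["9"]
        seqs = {Role(r): s for r, s in info["sequences"].items()}
        built = model_pmhc(seqs, db)
        assert built.templates_used[0] == info["expected_ranking"][0]

    def test_model_pmhc_identity_cap_excludes_self(self, isolated_universe):
        db = isolated_universe["pmhc"]
        eid = db.ids()[0]
        seqs = db.entries[eid].structure.sequences()
        built = model_pmhc(
            seqs, db, SelectionConfig(identity_cap=0.999)
        )
        assert eid not in built.templates_used

    def test_model_tcr_identical_target_rmsd_zero(self, isolated_universe):
        db = isolated_universe["tcr"]
        eid = db.ids()[0]
        native = db.entries[eid].structure
        built = model_tcr(native.sequences(), db)
        assert component_rmsd(
            built.structure, native, Component.TCR
        ) == pytest.approx(0.0, abs=1e-9)

    def test_unregistered_external_backend_fails_with_diagnostics(
        self, isolated_universe
    ):
        db = isolated_universe["tcr"]
        eid = db.ids()[0]
        with pytest.raises(BackendError):
            model_tcr(
                db.entries[eid].structure.sequences(),
                db,
                backend="external:nonexistent",
            )

    def test_backend_contract_violation_detected(self, isolated_universe):
        db = isolated_universe["tcr"]
        eid = db.ids()[0]
        native = db.entries[eid].structure

        def bad_backend(job):
            from tcrpmhc.core import ComplexStructure

            return ComplexStructure(
                id="bad",
                kind=Kind.TCR,
                chains={
                    Role.TCRA: native.chain(Role.TCRA).copy(),
                    Role.TCRB: native.chain(Role.TCRB).copy(),
                },
            )

        def missing_chain_backend(job):
            structure = bad_backend(job)
            del structure.chains[Role.TCRB]
            structure.kind = Kind.TCR
            return structure

        register_backend("truncating", missing_chain_backend)
        with pytest.raises((ContractError, BackendError)):
            model_tcr(
                native.sequences(), db, backend="external:truncating"
            )


class TestAssembly:
    def test_native_submodels_and_native_template_reassemble_exactly(
        self, isolated_universe
    ):
        db = isolated_universe["tcrpmhc"]
        eid = db.ids()[0]
        native = db.entries[eid].structure
        pmhc = extract_submodel(native, Kind.PMHC, db.profiles)
        tcr = extract_submodel(native, Kind.TCR, db.profiles)
        assembled = assemble_complex(tcr, pmhc, db)
        assert component_rmsd(
            assembled.structure, native, Component.TCRPMHC
        ) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_template_gives_same_model(self, isolated_universe):
        """Superposition-based assembly is invariant to a rigid transform
        of the complex template."""
        import copy as _copy

        from tcrpmhc.templatedb import TemplateDB, TemplateEntry

        db = isolated_universe["tcrpmhc"]
        eid = db.ids()[0]
        native = db.entries[eid].structure
        moved = native.copy()
        R = Rotation.from_euler("zyx", [1.1, 0.4, -2.0]).as_matrix()
        moved.transform(R, np.array([-20.0, 4.0, 7.0]))
        rotated_db = TemplateDB(
            kind=Kind.TCRPMHC,
            entries={
                eid: TemplateEntry(
                    structure=moved,
                    alignments=_copy.deepcopy(db.entries[eid].alignments),
                )
            },
            profiles=db.profiles,
        )
        pmhc = extract_submodel(native, Kind.PMHC, db.profiles)
        tcr = extract_submodel(native, Kind.TCR, db.profiles)
        assembled = assemble_complex(tcr, pmhc, rotated_db)
        assert component_rmsd(
            assembled.structure, native, Component.TCRPMHC
        ) == pytest.approx(0.0, abs=1e-6)

    def test_two_placements_average_to_midpoint(self, isolated_universe):
        """Equal-identity templates differing only by a TCR translation
        put the assembled TCR at the midpoint placement."""
        import copy as _copy

        from tcrpmhc.templatedb import TemplateDB, TemplateEntry

        db = isolated_universe["tcrpmhc"]
        eid = db.ids()[0]
        native = db.entries[eid].structure
        shifted = native.copy(new_id="shifted")
        delta = np.array([0.0, 0.0, 6.0])
        for role in (Role.TCRA, Role.TCRB):
            for res in shifted.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + delta
        # one TCRA substitution keeps the pair clearly below the
        # redundancy cutoff of 1.0 without moving any coordinate
        res0 = shifted.chain(Role.TCRA).residues[0]
        res0.name = "GLY" if res0.name != "GLY" else "ALA"
        from tcrpmhc.profiles import align_to_profile

        shifted_alns = _copy.deepcopy(db.entries[eid].alignments)
        shifted_alns[Role.TCRA] = align_to_profile(
            shifted.chain(Role.TCRA).sequence, db.profiles[Role.TCRA]
        )
        two_db = TemplateDB(
            kind=Kind.TCRPMHC,
            entries={
                eid: db.entries[eid],
                "shifted": TemplateEntry(
                    structure=shifted, alignments=shifted_alns
                ),
            },
            profiles=db.profiles,
        )
        pmhc = extract_submodel(native, Kind.PMHC, db.profiles)
        tcr = extract_submodel(native, Kind.TCR, db.profiles)
        assembled = assemble_complex(
            tcr, pmhc, two_db, SelectionConfig(redundancy_cutoff=1.0)
        )
        # identity-weighted mean of the two placements
        n_tcra = len(native.chain(Role.TCRA))
        w_native = 1.0
        w_shifted = 1.0 - (1.0 / n_tcra) / 6.0
        expected_shift = delta * w_shifted / (w_native + w_shifted)
        for role in (Role.TCRA, Role.TCRB):
            got = assembled.structure.chain(role).ca_array()
            want = native.chain(role).ca_array() + expected_shift
            assert np.max(np.linalg.norm(got - want, axis=1)) < 1e-6

    def test_internal_geometry_is_preserved(self, universe):
        """Assembly moves sub-models rigidly: intra-component Cα distance
        matrices are unchanged."""
        db = universe["tcrpmhc"]
        eid = db.ids()[3]
        native = db.entries[eid].structure
        pmhc = extract_submodel(native, Kind.PMHC, db.profiles)
        tcr = extract_submodel(native, Kind.TCR, db.profiles)
        assembled = assemble_complex(
            tcr, pmhc, db, SelectionConfig(), exclude=[eid]
        )
        for sub in (pmhc, tcr):
            cas_before = np.vstack(
                [sub.structure.chain(r).ca_array() for r in sub.structure.roles]
            )
            cas_after = np.vstack(
                [
                    assembled.structure.chain(r).ca_array()
                    for r in sub.structure.roles
                ]
            )
            d_before = np.linalg.norm(
                cas_before[:, None] - cas_before[None], axis=-1
            )
            d_after = np.linalg.norm(
                cas_after[:, None] - cas_after[None], axis=-1
            )
            assert np.max(np.abs(d_before - d_after)) < 1e-6


class TestPipeline:
    def test_self_target_reproduces_native(self, isolated_universe):
        db_c = isolated_universe["tcrpmhc"]
        eid = db_c.ids()[0]
        native = db_c.entries[eid].structure
        fasta = write_fasta(native.sequences(), name=eid)
        model, report = run_pipeline(
            fasta,
            isolated_universe["pmhc"],
            isolated_universe["tcr"],
            db_c,
        )
        for comp in Component:
            assert component_rmsd(
                model.structure, native, comp
            ) == pytest.approx(0.0, abs=1e-6)
        assert set(report["stages"]) == {"pmhc", "tcr", "assembly"}

    def test_overlong_peptide_rejected_before_modelling(self, universe):
        from tcrpmhc.fixtures import make_toy_complex

        base = make_toy_complex(seed=50)
        seqs = base.sequences()
        seqs[Role.PEPTIDE] = seqs[Role.PEPTIDE] + "AAA"  # 12-mer
        fasta = write_fasta(seqs)
        with pytest.raises(InputError):
            run_pipeline(
                fasta, universe["pmhc"], universe["tcr"], universe["tcrpmhc"]
            )

    def test_missing_role_record_names_it(self, universe):
        from tcrpmhc.fixtures import make_toy_complex

        base = make_toy_complex(seed=51)
        seqs = base.sequences()
        del seqs[Role.TCRB]
        with pytest.raises(InputError, match="TCRB"):
            run_pipeline(
                write_fasta(seqs),
                universe["pmhc"],
                universe["tcr"],
                universe["tcrpmhc"],
            )

    def test_rigid_invariance_of_whole_template_universe(
        self, isolated_universe
    ):
        """Rotating every template (all three databases) leaves the
        model-to-native RMSD unchanged."""
        import copy as _copy

        from tcrpmhc.templatedb import TemplateDB, TemplateEntry

        R = Rotation.from_euler("xyz", [0.7, 1.9, -0.3]).as_matrix()
        t = np.array([3.0, -8.0, 15.0])

        def rotated(db):
            out = TemplateDB(kind=db.kind, profiles=db.profiles)
            for eid, entry in db.entries.items():
                moved = entry.structure.copy()
                moved.transform(R, t)
                out.entries[eid] = TemplateEntry(
                    structure=moved,
                    alignments=_copy.deepcopy(entry.alignments),
                )
            return out

        db_c = isolated_universe["tcrpmhc"]
        target = db_c.ids()[1]
        native = db_c.entries[target].structure
        fasta = write_fasta(native.sequences(), name=target)
        config = SelectionConfig(identity_cap=0.999)
        model_a, _ = run_pipeline(
            fasta,
            isolated_universe["pmhc"],
            isolated_universe["tcr"],
            db_c,
            config,
            exclude=[target],
        )
        model_b, _ = run_pipeline(
            fasta,
            rotated(isolated_universe["pmhc"]),
            rotated(isolated_universe["tcr"]),
            rotated(db_c),
            config,
            exclude=[target],
        )
        rmsd_a = component_rmsd(model_a.structure, native, Component.TCRPMHC)
        rmsd_b = component_rmsd(model_b.structure, native, Component.TCRPMHC)
        assert rmsd_a == pytest.approx(rmsd_b, abs=1e-6)
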