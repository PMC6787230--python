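"""Model a TCR-pMHC complex end-to-end from sequences.

Builds a small synthetic template universe, takes the sequences of one
entry as the modelling target, runs the three-stage pipeline (pMHC model,
TCR model, assembly) and reports the accuracy against the known native
structure.  Because the target has a perfect template in the database,
every RMSD should print as 0 and DockQ as 1.
"""

from tcrpmhc import (
    FixtureSpec,
    SelectionConfig,
    evaluate_model,
    make_template_universe,
    run_pipeline,
    write_fasta,
)

# remote identities (<= 0.75) keep every other template below the 80%
# admission floor, so the perfect template is used alone
spec = FixtureSpec(
    seed=5,
    n_entries=8,
    peptide_lengths={9: 8},
    identity_targets=(0.99, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50, 0.45),
)
pmhc_db, tcr_db, tcrpmhc_db, manifest = make_template_universe(spec)

target_id = tcrpmhc_db.ids()[0]
native = tcrpmhc_db.entries[target_id].structure
fasta = write_fasta(native.sequences(), name=target_id)

model, report = run_pipeline(
    fasta, pmhc_db, tcr_db, tcrpmhc_db, SelectionConfig()
)

from tcrpmhc import Role

print(f"target: {target_id}  (peptide {native.sequences()[Role.PEPTIDE]})")
for stage, info in report["stages"].items():
    print(f"  {stage}: templates {info['selection']}")

metrics = evaluate_model(model.structure, native)
print("accuracy vs native:")
for key, value in metrics.items():
    print(f"  {key}: {value if isinstance(value, str) else round(value, 4)}")
print(
    "\nRMSDs are in Å (0 = atom-perfect rebuild); TM-score and DockQ are\n"
    "similarity scores in [0, 1] where 1 means the model matches the native\n"
    "structure exactly, including the TCR-pMHC interface."
)
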