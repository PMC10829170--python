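"""The three DDI evaluation schemes: random, one-unseen and both-unseen.

Task 1 (random, stratified 80:10:10) tests unseen pairs of known drugs;
Task 2 holds out drugs and tests pairs with exactly one new drug; Task 3
tests pairs of two new drugs. Tasks 2 and 3 share the same training
examples so results are directly comparable.
"""

import ddikit as dk

cfg = dk.FixtureConfig(n_scaffold_families=8, per_family=25, n_pairs=1000, seed=0)
library = dk.generate_molecule_library(cfg)
pairs = dk.generate_ddi_dataset(library, cfg)

task1 = dk.stratified_random_split(pairs, (0.8, 0.1, 0.1), seed=0)
print("Task 1 (random):    ", len(task1.train_ids), "train /",
      len(task1.val_ids), "val /", len(task1.test_ids), "test")

task2, task3 = dk.unseen_drug_splits(pairs, holdout_fraction=0.15, seed=0)
print("held-out 'new' drugs:", len(task2.holdout_drugs))
print("Task 2 (one-unseen):", len(task2.train_ids), "train /",
      len(task2.val_ids), "val /", len(task2.test_ids), "test")
print("Task 3 (both-unseen):", len(task3.train_ids), "train /",
      len(task3.val_ids), "val /", len(task3.test_ids), "test")

for spec in (task1, task2, task3):
    spec.validate(pairs)  # machine-checks the bucket invariants
print("\nall bucket invariants hold; tasks 2 and 3 share the training set:",
      task2.train_ids == task3.train_ids)

# MaxMin diversity split, used for the pre-training validation set
fps = [dk.circular_fingerprint(m.smiles_canonical) for m in library[:50]]
selected, remainder = dk.maxmin_split(fps, select_fraction=0.2, seed=0)
print("MaxMin picked", len(selected), "diverse molecules of", len(fps))
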