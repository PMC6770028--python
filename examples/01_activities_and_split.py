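"""Convert IC50 values to pIC50 with censoring and split train/test.

Activities above the 100 μM assay limit are kept as inactive records
pinned at pIC50 = 5; the split keeps 10% of the training-set size aside
while preserving the activity span and family coverage of both sets.
"""

from pycomfa import ic50_to_pic50, split_train_test
from pycomfa.activities import ActivityRecord

for ic50 in (1.0, 100.0, 150_000.0):
    pic50, censored = ic50_to_pic50(ic50)
    tag = " (censored: above the assay limit)" if censored else ""
    print(f"IC50 {ic50:>9.0f} nM -> pIC50 {pic50:.1f}{tag}")

# a toy activity table: 176 compounds, two families, activities 5..9.4,
# with a censored inactive tail pinned at exactly 5.0
records = []
for k in range(176):
    pic = min(4.5 + 5.1 * ((k * 37) % 176) / 175, 9.4)
    censored = pic <= 5.0
    pic = max(pic, 5.0)
    fam = ("benzamide", "arylpiperazine")[k % 2]
    ic50 = None if censored else 10 ** (9 - pic)
    records.append(ActivityRecord(f"c{k:03d}", ic50, pic, censored, fam))

split = split_train_test(records, fraction=0.10, seed=42)
print(f"\nsplit: {len(split.training_ids)} train / {len(split.test_ids)} test")
print("the 16-compound test set is 10% of the 160-compound training set,")
print("and both sets span the full 5..9+ activity range.")
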