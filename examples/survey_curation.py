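"""Curate a small survey: glottocode dedupe, largest-per-language, summary.

The dedupe rule is deliberately conservative: when two records for one
glottocode disagree in parity, the record *contradicting* the predicted
parity is kept, so duplicated sources can never manufacture evidence for
the hypothesis.
"""

import catsym as cs

records = [
    cs.SystemRecord("warlpiri", "warl1254", "Pama-Nyungan", "social", 8, "a"),
    cs.SystemRecord("warlpiri", "warl1254", "Pama-Nyungan", "social", 4, "b"),
    cs.SystemRecord("alyawarr", "alya1239", "Pama-Nyungan", "social", 4, "a"),
    cs.SystemRecord("alyawarr", "alya1239", "Pama-Nyungan", "social", 8, "b"),
    cs.SystemRecord("wajarri", "waja1257", "Pama-Nyungan", "cardinal", 4, "a"),
    cs.SystemRecord("wajarri2", "waja1257", "Pama-Nyungan", "cardinal", 3, "b"),
    cs.SystemRecord("mystery", "", "unknown", "cardinal", 5, "c"),
]

social = [r for r in records if r.domain == "social"]
largest = cs.largest_per_language(social)
print("largest-per-language keeps:",
      [(r.language, r.size) for r in largest])
summary = cs.parity_summary(largest)
print(f"social summary: n_even={summary.n_even}, n_odd={summary.n_odd}, "
      f"all powers of two: {summary.all_powers_of_two}")

cardinal = [r for r in records if r.domain == "cardinal"]
deduped = cs.dedupe_by_glottocode(cardinal, predicted_parity="even")
print("dedupe (predicted even) keeps:",
      [(r.glottocode or "<none>", r.size) for r in deduped])
print("waja1257 keeps size 3: with conflicting duplicates the odd record "
      "is kept, against the even prediction.")
flagged = [r.language for r in deduped if r.excluded_from_regression]
print(f"flagged as excluded from regression (no glottocode): {flagged}")
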