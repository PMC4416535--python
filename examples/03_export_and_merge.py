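"""Desktop-side tooling: back up a campaign, convert it to a workbook, merge files.

Merging a campaign file with a copy of itself demonstrates the
content-based de-duplication: every row is recognised as already present.
"""

import tempfile
from pathlib import Path

from antfield import CampaignSpec, backup, convert_to_workbook, generate_campaign, merge

workdir = Path(tempfile.mkdtemp())

campaign = generate_campaign(CampaignSpec(seed=42), workdir / "campaign.sqlite")

copy = workdir / "exported_copy.sqlite"
copy.write_bytes(campaign.read_bytes())

saved = backup(campaign, workdir)
print(f"backup written:   {saved.name}  (timestamp-named, collision-proof)")

written = convert_to_workbook(campaign, workdir / "campaign.xlsx", format="xlsx")
print(f"workbook written: {written[0].name}  (one sheet per table)")

report = merge([campaign, copy], workdir / "merged.sqlite")
print(f"\nmerge of a file with its own copy ({report.files_in} inputs):")
for table in report.rows_in:
    print(
        f"  {table:12s} in {report.rows_in[table]:4d}  "
        f"dropped {report.duplicates_dropped[table]:4d}  out {report.rows_out[table]:4d}"
    )
# rows_out equals the original counts: duplicate content is stored once.
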