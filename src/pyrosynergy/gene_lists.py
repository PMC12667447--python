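"""Published gene lists used by the screening funnel.

``BLBC_PYROPTOSIS_REGULATORS``: the 28 pyroptosis-related genes found
differentially expressed between basal-like breast cancer and normal
breast tissue in the TCGA cohort.  ``NCI60_UNMEASURED``: the 8 of them
with no expression data in the NCI-60 panel, leaving 20 regulators for
the drug-activity correlation screen.
"""

BLBC_PYROPTOSIS_REGULATORS: tuple[str, ...] = (
    "AIM2", "BCL2", "CGAS", "CTSV", "CXCL8", "DNMT3B", "GBP5", "GSDMC",
    "H2AZ1", "H2BC6", "H2BC9", "H3C12", "H4C3", "H4C4", "HTRA1", "IKBKE",
    "IL1A", "NLRP3", "NLRP6", "NOS1", "PARP1", "PRKN", "TNF", "TP63",
    "TREM1", "TREM2", "TXNIP", "ZBP1",
)

NCI60_UNMEASURED: tuple[str, ...] = (
    "CGAS", "H2AZ1", "H2BC6", "H2BC9", "H3C12", "H4C3", "H4C4", "PRKN",
)

# mouse/human ortholog aliases seen across the two expression systems
DEFAULT_ALIASES: dict[str, str] = {"CTSL": "CTSV"}
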