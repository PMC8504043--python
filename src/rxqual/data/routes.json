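{
  "version": "routes-1.0",
  "comment": "Administration-route vocabulary. Tokens are normalised by lowercasing and stripping hyphens/spaces before lookup. Any token with the prefix 'intra' is treated as a risky route in addition to the explicit list.",
  "vocabulary": [
    "peroral",
    "transdermal",
    "ocular",
    "nasal",
    "sublingual",
    "buccal",
    "rectal",
    "vaginal",
    "inhalative",
    "cutaneous",
    "auricular",
    "endotracheal",
    "endo-cervical",
    "epidural",
    "epilesional",
    "extra-amniotic",
    "gastrointestinal",
    "gingival",
    "laryngopharyngeal",
    "ossal",
    "para-cervical",
    "periarticular",
    "peribulbar",
    "perineural",
    "periosteal",
    "retrobulbar",
    "sub-tenon",
    "subconjunctival",
    "subcutaneous",
    "sublesional",
    "submucosal",
    "urethral",
    "via-probe",
    "intravenous",
    "intramuscular",
    "intraarterial",
    "intraarticular",
    "intrathecal",
    "intravesical",
    "intradermal",
    "intravitreal",
    "intraosseous",
    "intraperitoneal"
  ],
  "risky_routes": [
    "endotracheal",
    "endo-cervical",
    "epidural",
    "epilesional",
    "extra-amniotic",
    "gastrointestinal",
    "gingival",
    "laryngopharyngeal",
    "ossal",
    "para-cervical",
    "periarticular",
    "peribulbar",
    "perineural",
    "periosteal",
    "retrobulbar",
    "sub-tenon",
    "subconjunctival",
    "subcutaneous",
    "sublesional",
    "submucosal",
    "urethral",
    "via-probe"
  ],
  "risky_prefixes": ["intra"]
}
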