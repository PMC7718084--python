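# Seed-term algebraic expressions for ICF environmental-factor subcategories.
# Each query evaluates sum(v(plus)) - sum(v(minus)) against a trained
# embedding and reports the k nearest vocabulary terms (seed words excluded).
# Codes follow the ICF coding scheme; edit freely to retarget the analysis.
chapters:
  - code: e1
    label: products and technology
    queries:
      - {code: e1100, label: food, plus: [food, cholesterol], k: 6}
      - {code: e110, label: food and drugs (celiac), plus: [celiac, analysis], k: 6}
      - {code: e1101, label: drugs, plus: [drug, medicinal], k: 6}
      - {code: e1151, label: "assistive products, specially designed (voice)", plus: [voice, controlled], k: 6}
      - {code: e115, label: assistive products (speech), plus: [speech, app], k: 6}
      - {code: e1201, label: outdoor mobility products, plus: [motor, outdoor, power], k: 6}
      - {code: e1200, label: indoor transfer devices, plus: [transfer, indoor, device], k: 6}
      - {code: e120, label: mobility and transportation services, plus: [taxi, wheelchair], k: 6}
      - {code: e1401, label: "adapted equipment for culture, recreation and sport", plus: [adapted, sport], k: 6}
      - {code: e1501, label: outdoor wayfinding, plus: [wheelchair, apps], k: 6}
  - code: e2
    label: natural environment and human-made changes to environment
    queries:
      - {code: e225, label: climate, plus: [weather, temperature], k: 6}
      - {code: e240, label: light, plus: [light, glare], k: 6}
      - {code: e250, label: sound, plus: [noise, hearing], k: 6}
  - code: e3
    label: support and relationships
    queries:
      - {code: e310, label: immediate family, plus: [family, support], k: 6}
      - {code: e398, label: "support and relationships, other specified", plus: [support, relationships], k: 6}
  - code: e4
    label: attitudes
    queries:
      - {code: e460, label: societal attitudes, plus: [stigma, attitudes], k: 6}
      - {code: e450, label: attitudes of health professionals, plus: [doctor, attitude], k: 6}
  - code: e5
    label: services, systems and policies
    queries:
      - {code: e555, label: associations and organizational services, plus: [hear, association, kid], k: 6}
      - {code: e570, label: social security services, plus: [benefits, ssdi], k: 6}
      - {code: e580, label: health services, plus: [insurance, medicaid], k: 6}
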