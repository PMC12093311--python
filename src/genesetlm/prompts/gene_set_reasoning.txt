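List all the known genes directly and indirectly involved in the following biological process or cellular component """{descr}""". Use the following JSON schema:

```json
{{
 "type": "array",
 "items": {{
  "type": "object",
  "properties": {{
   "gene": {{
    "type": "string"
   }},
   "reason": {{
    "type": "string"
   }}
  }},
  "required": ["gene", "reason"]
 }}
}}
```

The field "gene" is a gene involved in the following biological process or cellular component: """{descr}""". Use the HUGO Gene Nomenclature Committee (HGNC) gene abbreviations. The field "reason" is a single sentence giving the rationale for why the gene is involved in the biological process or cellular component. Place the output in a JSON code block. Do not add any comments in the JSON code block.
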