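{
 "alpha_basal": {
  "1": 0.17471068907925238,
  "2": 0.001053060913114945,
  "3": 0.16424568367655326,
  "4": 0.5395796377428828,
  "5": 0.09358699056874416
 },
 "delta_m": {
  "1": 0.874787062362986,
  "2": 0.9188241016887755,
  "3": 0.9847942358727081,
  "4": 0.9197453897353562,
  "5": 0.5337200184977245
 },
 "graph": {
  "edges": [
   {
    "sign": 1,
    "source": 1,
    "target": 2
   },
   {
    "sign": 1,
    "source": 1,
    "target": 3
   },
   {
    "sign": 1,
    "source": 2,
    "target": 1
   },
   {
    "sign": 1,
    "source": 2,
    "target": 3
   },
   {
    "sign": -1,
    "source": 2,
    "target": 4
   },
   {
    "sign": -1,
    "source": 3,
    "target": 5
   },
   {
    "sign": 1,
    "source": 4,
    "target": 5
   }
  ],
  "labels": {
   "1": "E1",
   "2": "COL1a",
   "3": "FT4",
   "4": "FT2a",
   "5": "AP1a"
  },
  "n_vertices": 5
 },
 "h": {
  "1->2": 2,
  "1->3": 2,
  "2->1": 2,
  "2->3": 2,
  "2->4": 2,
  "3->5": 2,
  "4->5": 2
 },
 "k": {
  "1->2": 0.5579623785537475,
  "1->3": 0.9955452806000488,
  "2->1": 0.7947353000216155,
  "2->3": 0.625957437146751,
  "2->4": 0.9890705462050661,
  "3->5": 0.22315561125324296,
  "4->5": 0.1686099135192661
 },
 "modules": [
  {
   "activators": [
    2
   ],
   "beta": 0.7000763732837336,
   "c": 1,
   "deactivators": [],
   "inputs": [
    2
   ],
   "r": 0,
   "target": 1
  },
  {
   "activators": [
    1
   ],
   "beta": 0.9177710407756605,
   "c": 1,
   "deactivators": [],
   "inputs": [
    1
   ],
   "r": 0,
   "target": 2
  },
  {
   "activators": [
    1,
    2
   ],
   "beta": 0.8205485521961549,
   "c": 1,
   "deactivators": [],
   "inputs": [
    1,
    2
   ],
   "r": 0,
   "target": 3
  },
  {
   "activators": [
    2
   ],
   "beta": 0.3801657519924735,
   "c": -1,
   "deactivators": [],
   "inputs": [
    2
   ],
   "r": 0,
   "target": 4
  },
  {
   "activators": [
    4
   ],
   "beta": 0.44013302792898035,
   "c": 1,
   "deactivators": [
    3
   ],
   "inputs": [
    3,
    4
   ],
   "r": 0,
   "target": 5
  }
 ],
 "production": "clip",
 "rho": {
  "1": 0.9545486402289702,
  "2": 0.91763841815116,
  "3": 0.8823043814811868,
  "4": 1.1676144588239699,
  "5": 1.2568223884369298
 },
 "schema_version": 1,
 "seed": 7
}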