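# Default pathology taxonomy for breast masses.
#
# Schema: disease -> {ptype, malignancy, grade?}
#   ptype      pathological-type group the disease belongs to
#   malignancy benign | malignant
#   grade      integer degree of malignancy (malignant diseases only;
#              higher = more malignant), used by per-side mass selection
#
# The pathological-type grouping is this package's own working grouping of
# common breast-mass pathologies; sites with their own classification scheme
# should supply their own file with the same schema.

Acute suppurative mastitis:            {ptype: inflammatory lesion, malignancy: benign}
Granulomatous lobular mastitis:        {ptype: inflammatory lesion, malignancy: benign}
Mammary plasma cell mastitis:          {ptype: inflammatory lesion, malignancy: benign}
Breast abscess:                        {ptype: inflammatory lesion, malignancy: benign}
Intraductal papilloma of the breast:   {ptype: benign papillary lesion, malignancy: benign}
Radial sclerosing lesions of the breast: {ptype: sclerosing lesion, malignancy: benign}
Benign phyllodes tumor of the breast:  {ptype: fibroepithelial tumor, malignancy: benign}
Fibroepithelial tumor of the breast:   {ptype: fibroepithelial tumor, malignancy: benign}
Fibroadenoma of breast:                {ptype: fibroepithelial tumor, malignancy: benign}
Breast cyst:                           {ptype: cystic lesion, malignancy: benign}
Breast adenopathy:                     {ptype: adenosis, malignancy: benign}
Mammary hemangioma:                    {ptype: benign mesenchymal tumor, malignancy: benign}
Breast lipoma:                         {ptype: benign mesenchymal tumor, malignancy: benign}

Invasive ductal carcinoma of the breast:  {ptype: invasive non-specific carcinoma, malignancy: malignant, grade: 9}
Invasive lobular carcinoma of the breast: {ptype: invasive non-specific carcinoma, malignancy: malignant, grade: 8}
Breast neuroendocrine carcinoma:          {ptype: invasive specific carcinoma, malignancy: malignant, grade: 7}
Medullary breast cancer:                  {ptype: invasive specific carcinoma, malignancy: malignant, grade: 6}
Mucinous breast cancer:                   {ptype: invasive specific carcinoma, malignancy: malignant, grade: 5}
Adenoid cystic carcinoma of the breast:   {ptype: invasive specific carcinoma, malignancy: malignant, grade: 5}
Malignant mesenchymal tumor of the breast: {ptype: malignant mesenchymal tumor, malignancy: malignant, grade: 8}
Intraductal papillary carcinoma of the breast: {ptype: malignant papillary carcinoma, malignancy: malignant, grade: 4}
Intracystic papillary carcinoma:          {ptype: malignant papillary carcinoma, malignancy: malignant, grade: 4}
Ductal carcinoma in situ of the breast:   {ptype: carcinoma in situ, malignancy: malignant, grade: 3}
Borderline phyllodes tumor of the breast: {ptype: malignant fibroepithelial tumor, malignancy: malignant, grade: 2}
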